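import numpy as np
import pytest

from sipforest.dataset import AnnotationRecord
from sipforest.gcforest import CascadeSpec, ForestSpec, ScannerSpec


def random_records(n: int, seed: int) -> list[AnnotationRecord]:
    """Synthetic annotation records with all evidence fields exercised."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        records.append(
            AnnotationRecord(
                protein_id=f"P{i:05d}",
                length=int(rng.integers(1, 6001)),
                is_homo_oligomer=bool(rng.random() < 0.15),
                n_small_scale_experiments=int(rng.integers(0, 4)),
                n_large_scale_experiments=int(rng.integers(0, 4)),
                n_publications=int(rng.integers(0, 5)),
                has_any_interaction_annotation=bool(rng.random() < 0.4),
                is_annotated_sip=bool(rng.random() < 0.2),
            )
        )
    return records


def small_forests(n_trees: int = 15) -> tuple[ScannerSpec, CascadeSpec]:
    """Desk-scale forest specs: paper-structure forests with few trees."""
    scanner = ScannerSpec(
        window=100,
        stride=1,
        forests=(
            ForestSpec(kind="random", n_trees=n_trees),
            ForestSpec(kind="complete_random", n_trees=n_trees),
        ),
    )
    cascade = CascadeSpec(
        forests_per_level=(
            ForestSpec(kind="random", n_trees=n_trees),
            ForestSpec(kind="random", n_trees=n_trees),
            ForestSpec(kind="complete_random", n_trees=n_trees),
            ForestSpec(kind="complete_random", n_trees=n_trees),
        ),
        cv_folds=3,
        tolerance=5.0,
        max_levels=3,
    )
    return scanner, cascade


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
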