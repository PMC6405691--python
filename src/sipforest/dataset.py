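"""Golden-standard dataset construction for self-interacting proteins.

A *self-interacting protein* (SIP) is a protein whose copies bind each
other, forming homodimers, homotrimers or higher homo-oligomers.  Building
a labelled benchmark from interaction databases boils down to a small set
of deterministic filters over per-protein annotation records:

* a length filter that drops likely fragments (shorter than 50 residues)
  and unwieldy giants (longer than 5000 residues);
* a positive rule — a protein is a trusted SIP if it is annotated as a
  homo-oligomer, or its self-interaction has enough experimental support,
  or enough independent publications report it;
* a negative rule — a protein is a trusted non-SIP only if it carries no
  interaction annotation of any kind (direct interaction or the looser
  "physical association") and is not annotated as a SIP.

The filters here operate on pre-merged :class:`AnnotationRecord` rows; how
evidence from multiple source databases is merged into the per-protein
counts is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "AnnotationRecord",
    "GoldenStandardDataset",
    "length_filter",
    "select_positives",
    "select_negatives",
    "build_golden_standard",
    "read_annotation_table",
    "write_annotation_table",
    "write_golden_standard",
]

PositiveRuleVariant = Literal["strict", "lenient"]


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein's annotation evidence, merged across source databases.

    Attributes
    ----------
    protein_id
        Stable identifier (e.g. a UniProt accession).
    length
        Sequence length in residues; must be >= 1.
    is_homo_oligomer
        Whether the protein is annotated as a homo-oligomer (homodimer or
        homotrimer included).
    n_small_scale_experiments, n_large_scale_experiments
        Counts of experiments supporting the self-interaction.
    n_publications
        Number of publications reporting the self-interaction.
    has_any_interaction_annotation
        True if *any* interaction record exists for the protein, covering
        both "direct interaction" and the broader "physical association".
    is_annotated_sip
        True if the protein is annotated as a SIP in a curated resource.
    """

    protein_id: str
    length: int
    is_homo_oligomer: bool = False
    n_small_scale_experiments: int = 0
    n_large_scale_experiments: int = 0
    n_publications: int = 0
    has_any_interaction_annotation: bool = False
    is_annotated_sip: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        for name in (
            "n_small_scale_experiments",
            "n_large_scale_experiments",
            "n_publications",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GoldenStandardDataset:
    """Disjoint positive (SIP) and negative (non-SIP) protein-id lists."""

    positives: tuple[str, ...]
    negatives: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.positives)) != len(self.positives):
            raise ValueError("duplicate ids in positives")
        if len(set(self.negatives)) != len(self.negatives):
            raise ValueError("duplicate ids in negatives")
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:5]}")


def length_filter(
    records: Sequence[AnnotationRecord],
    min_len: int = 50,
    max_len: int = 5000,
) -> list[AnnotationRecord]:
    """Drop records outside ``[min_len, max_len]`` residues, keeping order.

    Removal is strict: only proteins shorter than ``min_len`` or longer
    than ``max_len`` are discarded, so the boundary lengths survive.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [r for r in records if min_len <= r.length <= max_len]


def _is_positive(record: AnnotationRecord, variant: PositiveRuleVariant) -> bool:
    if record.is_homo_oligomer:
        return True
    small_needed = 2 if variant == "strict" else 1
    if record.n_small_scale_experiments >= small_needed:
        return True
    if record.n_large_scale_experiments >= 2:
        return True
    return record.n_publications >= 3


def select_positives(
    records: Iterable[AnnotationRecord],
    variant: PositiveRuleVariant = "strict",
) -> list[str]:
    """Ids of proteins whose self-interaction evidence is strong enough.

    A protein qualifies if at least one clause holds:

    (a) it is annotated as a homo-oligomer;
    (b) enough experiments detected the self-interaction — under the
        default ``"strict"`` variant at least 2 small-scale or at least 2
        large-scale experiments, under ``"lenient"`` a single small-scale
        experiment already suffices;
    (c) more than two publications (i.e. >= 3) report it.

    The two variants exist because "more than one small-scale experiment
    or two large-scale experiments" admits both readings; the variant is a
    parameter rather than a silent choice.
    """
    if variant not in ("strict", "lenient"):
        raise ValueError(f"unknown positive_rule_variant: {variant!r}")
    return [r.protein_id for r in records if _is_positive(r, variant)]


def select_negatives(records: Iterable[AnnotationRecord]) -> list[str]:
    """Ids of proteins with no interaction annotation whatsoever.

    The negative rule is deliberately aggressive: any interaction record
    (including mere "physical association"), any SIP annotation, and any
    record satisfying a positive clause disqualifies a protein from the
    negative set.  In consistently curated data the flags alone imply the
    rest; checking the positive clauses as well keeps the positive and
    negative sets disjoint even for inconsistent inputs.
    """
    return [
        r.protein_id
        for r in records
        if not r.has_any_interaction_annotation
        and not r.is_annotated_sip
        and not _is_positive(r, "lenient")
    ]


def build_golden_standard(
    records: Sequence[AnnotationRecord],
    min_len: int = 50,
    max_len: int = 5000,
    variant: PositiveRuleVariant = "strict",
) -> GoldenStandardDataset:
    """Length-filter, then apply the positive and negative rules."""
    kept = length_filter(records, min_len=min_len, max_len=max_len)
    return GoldenStandardDataset(
        positives=tuple(select_positives(kept, variant=variant)),
        negatives=tuple(select_negatives(kept)),
    )


_BOOL_FIELDS = ("is_homo_oligomer", "has_any_interaction_annotation", "is_annotated_sip")


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """Read a TSV annotation table (booleans encoded as 0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    expected = {f.name for f in fields(AnnotationRecord)}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        kw = {name: getattr(row, name) for name in expected}
        for name in _BOOL_FIELDS:
            kw[name] = bool(int(kw[name]))
        for name in (
            "length",
            "n_small_scale_experiments",
            "n_large_scale_experiments",
            "n_publications",
        ):
            kw[name] = int(kw[name])
        records.append(AnnotationRecord(**kw))
    return records


def write_annotation_table(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write records as a TSV table with 0/1-encoded booleans."""
    cols = [f.name for f in fields(AnnotationRecord)]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    for name in _BOOL_FIELDS:
        df[name] = df[name].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_golden_standard(ds: GoldenStandardDataset, path: str | Path) -> None:
    """Write a two-column TSV: protein_id, label (1 = SIP, 0 = non-SIP)."""
    rows = [(pid, 1) for pid in ds.positives] + [(pid, 0) for pid in ds.negatives]
    pd.DataFrame(rows, columns=["protein_id", "label"]).to_csv(path, sep="\t", index=False)
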