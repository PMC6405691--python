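"""Position-specific scoring matrices: parsing, scoring and synthesis.

A PSSM is an ``H x 20`` profile for a protein of ``H`` residues: row ``a``
scores each of the 20 standard amino acids at sequence position ``a``.
Strongly conserved positions score high for the conserved residue and low
elsewhere; weakly conserved positions are flat.

Profiles normally come from PSI-BLAST (typically run at E-value 0.001 for
three iterations against a large sequence database); this module does not
invoke PSI-BLAST but reads its ``-out_ascii_pssm`` output.  Two further
routes produce PSSM-shaped matrices without a database:

* :func:`dayhoff_score` converts an observed amino-acid frequency profile
  into substitution-weighted scores using a Dayhoff-family (PAM250)
  mutation matrix: ``C[a, b] = sum_k p(a, k) * q(b, k)``;
* :func:`synthesize_pssm` draws seeded random profiles with a tunable
  class-dependent mean shift, so the full downstream pipeline can be
  exercised offline.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ALPHABET",
    "PSSM",
    "FrequencyProfile",
    "MutationMatrix",
    "MalformedPSSMError",
    "pam250_matrix",
    "parse_pssm_file",
    "read_pssm_tsv",
    "write_pssm_tsv",
    "dayhoff_score",
    "synthesize_pssm",
]

#: Canonical amino-acid column order (the NCBI PSSM convention).
ALPHABET: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Columns of a synthetic PSSM that carry the class signal.
SIGNAL_COLUMNS = (0, 1, 2, 3, 4)


class MalformedPSSMError(ValueError):
    """Raised when an ASCII profile file cannot be parsed."""


@dataclass(frozen=True)
class PSSM:
    """An ``H x 20`` position-specific scoring matrix.

    ``scores[a, b]`` is the score of amino acid ``ALPHABET[b]`` at
    position ``a``; ``H`` equals the protein's residue count.
    """

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[1] != 20:
            raise ValueError(f"scores must be H x 20, got shape {s.shape}")
        if s.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if not np.all(np.isfinite(s)):
            raise ValueError("PSSM entries must be finite")
        object.__setattr__(self, "scores", s)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class FrequencyProfile:
    """Observed amino-acid frequencies per position (rows sum to 1)."""

    freqs: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 20:
            raise ValueError(f"freqs must be H x 20, got shape {f.shape}")
        if np.any(f < 0):
            raise ValueError("frequencies must be non-negative")
        if self.normalized and f.size:
            sums = f.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("frequency rows must sum to 1 (pass normalized=False to skip)")
        object.__setattr__(self, "freqs", f)


@dataclass(frozen=True)
class MutationMatrix:
    """A 20x20 amino-acid substitution score matrix (Dayhoff / PAM family)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (20, 20):
            raise ValueError(f"mutation matrix must be 20x20, got {q.shape}")
        if not np.all(np.isfinite(q)):
            raise ValueError("mutation matrix entries must be finite")
        object.__setattr__(self, "q", q)


def pam250_matrix() -> MutationMatrix:
    """The PAM250 substitution matrix restricted to the 20-letter alphabet."""
    pam = substitution_matrices.load("PAM250")
    idx = [pam.alphabet.index(a) for a in ALPHABET]
    q = np.asarray(pam)[np.ix_(idx, idx)].astype(float)
    return MutationMatrix(q=q)


_ROW_RE = re.compile(r"^\s*(\d+)\s+([A-Za-z*])\s+(-?\d.*)$")


def parse_pssm_file(source: str | Path | TextIO, protein_id: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` profile into a :class:`PSSM`.

    Only the first 20-column block (the log-odds scores) of each residue
    row is read; the trailing percentage block and per-row statistics are
    ignored.  If the header names the amino-acid columns, they are
    reordered to :data:`ALPHABET`; a file without a recognizable header is
    assumed to already use the NCBI column order.

    Raises
    ------
    MalformedPSSMError
        If no residue rows are found, or a residue row carries fewer than
        20 scores (the offending line number is reported).
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if protein_id is None:
            protein_id = path.stem.split(".")[0]
    else:
        text = source.read()
    if protein_id is None:
        protein_id = "unknown"

    column_order: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        m = _ROW_RE.match(line)
        if m is None:
            letters = stripped.split()
            # header naming the score columns: >= 20 single letters
            if column_order is None and len(letters) >= 20 and all(
                len(t) == 1 and t.isalpha() for t in letters[:20]
            ):
                column_order = letters[:20]
            continue
        fields = m.group(3).split()
        scores = []
        for tok in fields[:20]:
            try:
                scores.append(float(tok))
            except ValueError:
                break
        if len(scores) < 20:
            raise MalformedPSSMError(
                f"line {lineno}: expected 20 scores, found {len(scores)}"
            )
        rows.append(scores)

    if not rows:
        raise MalformedPSSMError("no residue rows found")

    scores = np.asarray(rows, dtype=float)
    if column_order is not None and tuple(column_order) != ALPHABET:
        order = [column_order.index(a) for a in ALPHABET]
        scores = scores[:, order]
    return PSSM(protein_id=protein_id, scores=scores)


def read_pssm_tsv(path: str | Path, protein_id: str | None = None) -> PSSM:
    """Read the internal TSV serialization (header row of amino-acid letters)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if tuple(header) != ALPHABET:
            raise MalformedPSSMError(f"{path}: unexpected header {header!r}")
        scores = np.loadtxt(fh, ndmin=2)
    if protein_id is None:
        protein_id = path.stem.split(".")[0]
    return PSSM(protein_id=protein_id, scores=scores)


def write_pssm_tsv(p: PSSM, path: str | Path) -> None:
    """Write a PSSM as TSV: one header row of letters, then H score rows."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(ALPHABET) + "\n")
        np.savetxt(fh, p.scores, delimiter="\t", fmt="%.10g")


def dayhoff_score(
    profile: FrequencyProfile,
    mutation: MutationMatrix,
    protein_id: str = "profile",
) -> PSSM:
    """Substitution-weighted position scores ``C[a, b] = sum_k p(a,k) q(b,k)``.

    The sum runs over the 20 amino acids ``k``; ``p`` is the observed
    frequency profile and ``q`` the mutation matrix.  In matrix form this
    is ``P @ Q.T``, which also makes the linearity of the operation in the
    profile explicit.
    """
    p = profile.freqs
    q = mutation.q
    if p.shape[1] != q.shape[0]:
        raise ValueError(f"profile has {p.shape[1]} columns, mutation matrix {q.shape[0]} rows")
    return PSSM(protein_id=protein_id, scores=p @ q.T)


def synthesize_pssm(
    length: int,
    class_label: int,
    signal_strength: float = 2.0,
    seed: int = 0,
    protein_id: str | None = None,
) -> PSSM:
    """Draw a synthetic PSSM with a class-dependent column-mean shift.

    Each row is i.i.d. standard Gaussian noise across the 20 columns.  For
    ``class_label == 1`` the mean of columns :data:`SIGNAL_COLUMNS` is
    shifted by ``signal_strength``, emulating the class-separating
    conservation signal a real profile would carry.  With
    ``signal_strength == 0`` the two classes are identically distributed.
    Fully reproducible from ``seed``.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if class_label not in (0, 1):
        raise ValueError(f"class_label must be 0 or 1, got {class_label}")
    if signal_strength < 0:
        raise ValueError("signal_strength must be >= 0")
    rng = np.random.default_rng(seed)
    scores = rng.normal(0.0, 1.0, size=(length, 20))
    if class_label == 1:
        scores[:, list(SIGNAL_COLUMNS)] += signal_strength
    if protein_id is None:
        protein_id = f"synth_{class_label}_{seed}"
    return PSSM(protein_id=protein_id, scores=scores)
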