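"""Fixed-length wavelet features from variable-length PSSMs.

Protein sequences differ in length, so an ``H x 20`` profile cannot feed a
fixed-width classifier directly.  The encoding used here first collapses
the length dimension by forming the 20x20 cross-product ``M.T @ M`` (a
symmetric positive-semidefinite summary of per-column co-conservation),
then applies one level of a 2-D orthonormal discrete wavelet transform.
The four 10x10 sub-bands — approximation, horizontal, vertical and
diagonal detail — are concatenated row-major into exactly 400
coefficients.  Because the transform is orthonormal, the coefficients
preserve the Frobenius mass of the input (Parseval identity), so nothing
is lost at this stage; principal-component analysis then drops the
lowest-variance directions, reducing 400 to 300 dimensions by default.

The wavelet family, level and boundary rule are parameters of
:class:`WaveletBasis`; the defaults (Haar, level 1, periodization) are the
simplest orthonormal choice that yields exactly 400 coefficients from a
20x20 input.  An alternative encoder emitting the 20 eigenvalues of the
cross-product is available via ``eigenvalue_features`` but is not the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.decomposition import PCA as _SKPCA

from .pssm import PSSM

__all__ = [
    "SquareProfile",
    "WaveletBasis",
    "FeatureVector",
    "PCAModel",
    "cross_product",
    "wavelet_features",
    "eigenvalue_features",
    "fit_pca",
    "apply_pca",
    "encode_pssms",
]


@dataclass(frozen=True)
class SquareProfile:
    """The 20x20 cross-product ``M.T @ M`` of a PSSM ``M``."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (20, 20):
            raise ValueError(f"square profile must be 20x20, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("square profile must be symmetric")
        object.__setattr__(self, "m", m)


@dataclass(frozen=True)
class WaveletBasis:
    """An orthonormal discrete wavelet basis for the 20x20 input.

    ``family`` must name an orthogonal pywt wavelet; ``level`` levels of
    decomposition with ``boundary_mode`` extension.  The default Haar /
    level 1 / periodization setup maps a 20x20 matrix onto four 10x10
    sub-bands.
    """

    family: str = "haar"
    level: int = 1
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        w = pywt.Wavelet(self.family)
        if not w.orthogonal:
            raise ValueError(f"wavelet {self.family!r} is not orthogonal")
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.level > pywt.dwt_max_level(20, w.dec_len):
            raise ValueError(f"level {self.level} too deep for a 20x20 input")


@dataclass(frozen=True)
class FeatureVector:
    """An ordered feature vector (400 wavelet coefficients, or 300 post-PCA)."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PCAModel:
    """Mean and orthonormal principal axes fitted on training vectors."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float)
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")
        gram = c @ c.T
        if not np.allclose(gram, np.eye(c.shape[0]), atol=1e-8):
            raise ValueError("component rows must be orthonormal")
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "components", c)
        object.__setattr__(self, "explained_variance", ev)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def cross_product(p: PSSM) -> SquareProfile:
    """``M.T @ M``: symmetric PSD 20x20 summary, independent of length H.

    Equivalently the sum over residue positions of the outer products of
    the PSSM's rows.
    """
    m = p.scores
    return SquareProfile(m=m.T @ m)


def wavelet_features(sp: SquareProfile, basis: WaveletBasis | None = None) -> FeatureVector:
    """Single-level 2-D DWT of the square profile, flattened to 400 values.

    Sub-bands are concatenated row-major in the order approximation,
    horizontal detail, vertical detail, diagonal detail.  For the default
    orthonormal basis the operation is linear in the input and satisfies
    the Parseval identity: the squared coefficients sum to the squared
    Frobenius norm of the input.
    """
    if basis is None:
        basis = WaveletBasis()
    if basis.level == 1:
        ca, (ch, cv, cd) = pywt.dwt2(sp.m, basis.family, mode=basis.boundary_mode)
        parts = [ca, ch, cv, cd]
    else:
        coeffs = pywt.wavedec2(sp.m, basis.family, mode=basis.boundary_mode, level=basis.level)
        parts = [coeffs[0]] + [band for lvl in coeffs[1:] for band in lvl]
    values = np.concatenate([part.ravel() for part in parts])
    return FeatureVector(protein_id="", values=values)


def eigenvalue_features(sp: SquareProfile) -> FeatureVector:
    """Alternative encoder: the 20 eigenvalues of the square profile, descending."""
    eig = np.linalg.eigvalsh(sp.m)[::-1]
    return FeatureVector(protein_id="", values=eig)


def fit_pca(vectors: np.ndarray, n_components: int = 300) -> PCAModel:
    """Fit mean-centred principal axes on rows of ``vectors``.

    Requires at least ``n_components + 1`` training vectors so the sample
    covariance can support the requested rank.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D array (n_samples x n_features)")
    n = X.shape[0]
    if n < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} training vectors for "
            f"{n_components} components, got {n}"
        )
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    sk.fit(X)
    return PCAModel(
        mean=sk.mean_,
        components=sk.components_,
        explained_variance=sk.explained_variance_,
    )


def apply_pca(model: PCAModel, v: FeatureVector | np.ndarray) -> FeatureVector | np.ndarray:
    """Project onto the principal axes: ``components @ (v - mean)``.

    Accepts a single :class:`FeatureVector` (returns one) or a 2-D array
    of row vectors (returns the projected array).  An orthonormal
    projection, hence non-expansive on the centred input.
    """
    if isinstance(v, FeatureVector):
        out = apply_pca(model, v.values[None, :])
        return FeatureVector(protein_id=v.protein_id, values=out[0])
    X = np.asarray(v, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.mean.size:
        raise ValueError(
            f"expected vectors of length {model.mean.size}, got shape {X.shape}"
        )
    return (X - model.mean) @ model.components.T


def encode_pssms(
    pssms: list[PSSM],
    basis: WaveletBasis | None = None,
    encoder: str = "wavelet",
) -> np.ndarray:
    """Encode a batch of PSSMs into a feature matrix (one row per protein)."""
    if encoder == "wavelet":
        rows = [wavelet_features(cross_product(p), basis).values for p in pssms]
    elif encoder == "eigenvalue":
        rows = [eigenvalue_features(cross_product(p)).values for p in pssms]
    else:
        raise ValueError(f"unknown encoder: {encoder!r}")
    return np.vstack(rows)
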