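"""Omic similarity kernels, kernel fusion, and the alignment hierarchy.

The similarity between two subjects in one molecular profile is their
biomarker-averaged inner product: for a subjects x biomarkers matrix Z_m
with p_m biomarkers the linear kernel is K_m = Z_m Z_m' / p_m.  Kernel
alignment is the cosine of the angle between two kernels under the
elementwise (Frobenius) inner product over all n^2 entries, so it lies in
[-1, 1] and equals 1 for identical kernels.  Applied twice the statistic
yields a hierarchy: profile alignment matrices (how similar the kernels
of two omic profiles are within a cohort) and cohort alignment (how
similar two cohorts' profile-alignment patterns are).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import OmicMatrix

__all__ = [
    "Kernel",
    "AlignmentMatrix",
    "build_linear_kernel",
    "matrix_alignment",
    "kernel_alignment",
    "profile_alignment_matrix",
    "cohort_alignment_matrix",
    "fuse_kernels",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class Kernel:
    """An n x n symmetric PSD omic similarity matrix."""

    values: pd.DataFrame  # index == columns == subject ids
    source_profile: str = "omic"
    p_m: int = 0

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("kernel must be square")
        if not list(self.values.index) == list(self.values.columns):
            raise ValueError("kernel row and column subject ids differ")
        if pd.Index(self.values.index).has_duplicates:
            raise ValueError("duplicate subject ids in kernel")
        asym = np.abs(arr - arr.T).max() if arr.size else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        w = np.linalg.eigvalsh((arr + arr.T) / 2.0)
        lam_max = max(w.max(), 0.0) if w.size else 0.0
        if w.size and w.min() < -_PSD_TOL * max(lam_max, 1.0):
            raise ValueError(
                f"kernel not positive semi-definite (min eigenvalue {w.min():.2e})"
            )

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(float)


@dataclass
class AlignmentMatrix:
    """Symmetric matrix of pairwise alignment statistics, unit diagonal."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if np.abs(arr).max() > 1 + 1e-8:
            raise ValueError("alignment entries must lie in [-1, 1]")

    @property
    def labels(self) -> list:
        return list(self.values.index)


def build_linear_kernel(Z: OmicMatrix) -> Kernel:
    """Linear kernel K = Z Z' / p_m of a preprocessed profile.

    Continuous profiles should be column-standardized first; binary
    mutation profiles enter raw, making diag(K) the per-subject mutation
    count divided by p_m (the normalized mutation burden).
    """
    p = Z.n_biomarkers
    if p == 0:
        raise ValueError("profile has no biomarkers")
    arr = Z.values.to_numpy(float)
    if np.isnan(arr).any():
        raise ValueError("profile contains missing values; impute first")
    K = arr @ arr.T / p
    K = (K + K.T) / 2.0
    df = pd.DataFrame(K, index=Z.values.index, columns=Z.values.index)
    return Kernel(df, source_profile=Z.profile_name, p_m=p)


def _frobenius(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(a * b))


def _alignment(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = _frobenius(a, a), _frobenius(b, b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("alignment undefined for an all-zero matrix")
    return _frobenius(a, b) / np.sqrt(na * nb)


def matrix_alignment(a, b) -> float:
    """Alignment of two same-shape matrices (arrays or DataFrames).

    The cosine statistic itself needs no positive semi-definiteness, so it
    also applies to negated or otherwise indefinite matrices; for kernels
    prefer :func:`kernel_alignment`, which additionally checks subject
    identity.
    """
    a = np.asarray(a, float) if not isinstance(a, pd.DataFrame) else a.to_numpy(float)
    b = np.asarray(b, float) if not isinstance(b, pd.DataFrame) else b.to_numpy(float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return _alignment(a, b)


def kernel_alignment(K1: Kernel, K2: Kernel) -> float:
    """Alignment A(K1, K2) = <K1,K2> / sqrt(<K1,K1><K2,K2>) in [-1, 1].

    The inner product sums over all n^2 entries, diagonal included.
    """
    if K1.subject_ids != K2.subject_ids:
        raise ValueError(
            f"subject mismatch between kernels {K1.source_profile!r} and "
            f"{K2.source_profile!r}"
        )
    return _alignment(K1.to_numpy(), K2.to_numpy())


def profile_alignment_matrix(kernels: Sequence[Kernel]) -> AlignmentMatrix:
    """Pairwise alignment of each omic profile's kernel within a cohort."""
    if len(kernels) < 2:
        raise ValueError("need at least two kernels")
    labels = [k.source_profile for k in kernels]
    n = len(kernels)
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            A[i, j] = A[j, i] = kernel_alignment(kernels[i], kernels[j])
    return AlignmentMatrix(pd.DataFrame(A, index=labels, columns=labels))


def cohort_alignment_matrix(
    profile_matrices: Sequence[AlignmentMatrix],
    cohort_labels: Sequence[str] | None = None,
) -> AlignmentMatrix:
    """Alignment of profile-alignment patterns across cohorts.

    Each cohort's profile-alignment matrix is restricted to the profiles
    shared by every cohort, vectorized (diagonal included), and the same
    cosine statistic is applied.  Values close to one mean two cohorts
    share a similar pattern of inter-profile similarity.
    """
    if len(profile_matrices) < 2:
        raise ValueError("need at least two cohorts")
    if cohort_labels is None:
        cohort_labels = [f"cohort{i + 1}" for i in range(len(profile_matrices))]
    shared = set(profile_matrices[0].labels)
    for m in profile_matrices[1:]:
        shared &= set(m.labels)
    if len(shared) < 2:
        raise ValueError("fewer than two profiles shared across cohorts")
    order = [lab for lab in profile_matrices[0].labels if lab in shared]
    mats = [m.values.loc[order, order].to_numpy(float) for m in profile_matrices]
    n = len(mats)
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            A[i, j] = A[j, i] = _alignment(mats[i], mats[j])
    return AlignmentMatrix(pd.DataFrame(A, index=list(cohort_labels), columns=list(cohort_labels)))


def fuse_kernels(kernels: Sequence[Kernel], weights: Sequence[float]) -> Kernel:
    """Weighted sum K = sum_m sigma2_m K_m of similarity matrices.

    Nonnegative weights keep the result PSD; in the fused Cox model the
    weights are the per-profile variance components.
    """
    if len(kernels) != len(weights):
        raise ValueError("one weight per kernel required")
    if any(w < 0 for w in weights):
        raise ValueError("kernel weights must be nonnegative")
    ids = kernels[0].subject_ids
    for k in kernels[1:]:
        if k.subject_ids != ids:
            raise ValueError("kernels must share subject ids and order")
    fused = np.zeros((len(ids), len(ids)))
    for k, w in zip(kernels, weights):
        fused += w * k.to_numpy()
    name = "+".join(k.source_profile for k in kernels)
    df = pd.DataFrame(fused, index=ids, columns=ids)
    return Kernel(df, source_profile=name, p_m=sum(k.p_m for k in kernels))
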