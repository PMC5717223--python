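"""Model evaluation: C-index, Monte Carlo cross-validation, external
validation, and down-sampling experiments.

The sole metric is Harrell's concordance index: among comparable subject
pairs (the earlier time is an observed event and the times differ), the
proportion in which the shorter-surviving subject received the larger
risk score, with risk ties counting one half.  Monte Carlo
cross-validation repeatedly splits subjects 80/20, preprocesses and fits
on the training split only, and scores the validation split — no
validation information ever reaches the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _lifelines_cindex

from .baselines import (
    ClinicalCoxMethod,
    GeneListSignatureMethod,
    KernelMethod,
    LassoMethod,
    _apply_stats,
)
from .io import BINARY, OmicMatrix, SurvivalOutcome, standardize_profile
from .meta import CIndexTable
from .model import KernelCoxPHResults

__all__ = [
    "concordance_index",
    "CVResult",
    "monte_carlo_cv",
    "make_method",
    "external_validate",
    "DownsampleGrid",
    "downsample_experiment",
    "cv_results_to_table",
]


def concordance_index(outcome: SurvivalOutcome, risk: np.ndarray) -> float:
    """Harrell's C of hazard-direction risk scores against censored times.

    Larger risk should pair with shorter survival; C = 1 is perfect
    ranking, 0.5 is chance.
    """
    risk = np.asarray(risk, float)
    if len(risk) != len(outcome.subject_ids):
        raise ValueError("risk scores and outcome lengths differ")
    try:
        # lifelines orients scores as 'higher predicts longer survival'
        return float(_lifelines_cindex(outcome.time, -risk, outcome.event))
    except ZeroDivisionError as err:
        raise ValueError("no comparable pairs in outcome") from err


@dataclass
class CVResult:
    """Per-repeat C-indices of one method under Monte Carlo CV."""

    method: str
    cindices: list
    train_frac: float
    repeats: int
    base_seed: int
    skipped: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.cindices))

    @property
    def sd(self) -> float:
        return float(np.std(self.cindices, ddof=1)) if len(self.cindices) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "repeat": range(len(self.cindices)),
                "cindex": self.cindices,
            }
        )


def make_method(spec: str, seed: int = 0, **kwargs):
    """Build a comparator from a short spec string.

    Specs: ``"clinical"``, ``"kernel:mRNA"``, ``"kernel:mRNA+miRNA"``,
    ``"kernel+clinical:mRNA"``, ``"lasso:mRNA"``, ``"signature"`` (needs
    ``gene_lists=`` in kwargs).
    """
    head, _, arg = spec.partition(":")
    names = arg.split("+") if arg else None
    if head == "clinical":
        return ClinicalCoxMethod()
    if head == "kernel":
        return KernelMethod(profile_names=names, **kwargs)
    if head == "kernel+clinical":
        return KernelMethod(profile_names=names, with_clinical=True, **kwargs)
    if head == "lasso":
        return LassoMethod(profile_name=names[0] if names else None, seed=seed, **kwargs)
    if head == "signature":
        return GeneListSignatureMethod(profile_name=names[0] if names else None, **kwargs)
    raise ValueError(f"unknown method spec {spec!r}")


def _split_dataset(dataset, subject_ids):
    outcome = dataset.outcome.subset_subjects(subject_ids)
    clinical = dataset.clinical.subset_subjects(subject_ids) if dataset.clinical is not None else None
    profiles = [Z.subset_subjects(subject_ids) for Z in dataset.profiles]
    return outcome, clinical, profiles


def monte_carlo_cv(
    dataset,
    method,
    repeats: int = 100,
    train_frac: float = 0.8,
    base_seed: int = 0,
) -> CVResult:
    """Repeated random 80/20 split evaluation of one method.

    ``dataset`` needs attributes ``outcome``, ``clinical`` (may be None)
    and ``profiles``; ``method`` is a comparator object (see
    :func:`make_method`) or a spec string.  Split r uses seed
    ``base_seed + r``.  Repeats whose validation split has no event are
    skipped and logged; more than 20% skipped is an error.
    """
    if isinstance(method, str):
        method = make_method(method, seed=base_seed)
    ids = np.asarray(dataset.outcome.subject_ids)
    n = len(ids)
    if n < 25:
        raise ValueError("need at least 25 subjects for Monte Carlo CV")
    n_train = int(round(train_frac * n))
    cindices, skipped = [], []
    for r in range(repeats):
        rng = np.random.default_rng(base_seed + r)
        perm = rng.permutation(n)
        tr_ids, va_ids = list(ids[perm[:n_train]]), list(ids[perm[n_train:]])
        va_outcome = dataset.outcome.subset_subjects(va_ids)
        if va_outcome.n_events == 0:
            skipped.append(r)
            continue
        tr = _split_dataset(dataset, tr_ids)
        va = _split_dataset(dataset, va_ids)
        method.fit(*tr)
        risk = method.score(va[1], va[2])
        try:
            cindices.append(concordance_index(va_outcome, risk))
        except ValueError as err:
            if "no comparable pairs" not in str(err):
                raise
            skipped.append(r)
    if len(skipped) > 0.2 * repeats:
        raise ValueError(
            f"{len(skipped)}/{repeats} repeats had event-free validation splits "
            "or no comparable validation pairs"
        )
    return CVResult(
        method=getattr(method, "name", str(method)),
        cindices=cindices,
        train_frac=train_frac,
        repeats=repeats,
        base_seed=base_seed,
        skipped=skipped,
    )


def external_validate(
    results: KernelCoxPHResults,
    external,
    min_overlap: float = 0.5,
) -> tuple[float, dict]:
    """Score a fitted kernel model on an external cohort.

    External profiles are intersected with the training biomarkers (the
    overlap must reach ``min_overlap`` per profile), transformed with the
    frozen training statistics, and scored; returns the single external
    C-index and an intersection report.
    """
    model = results.model
    if model.profiles is None:
        raise ValueError("model must be built from profiles for external validation")
    stats = model.stats
    report = {}
    processed = []
    train_sub = []
    for Zt in model.profiles:
        Ze = next(Z for Z in external.profiles if Z.profile_name == Zt.profile_name)
        shared = [b for b in Zt.biomarker_ids if b in Ze.values.columns]
        overlap = len(shared) / Zt.n_biomarkers
        report[Zt.profile_name] = {"shared": len(shared), "overlap": overlap}
        if overlap < min_overlap:
            raise ValueError(
                f"biomarker overlap {overlap:.0%} below the {min_overlap:.0%} floor "
                f"for profile {Zt.profile_name!r}"
            )
        Ze = Ze.subset_biomarkers(shared)
        Zt_sub = Zt.subset_biomarkers(shared)
        st = stats.get(Zt.profile_name)
        if st is not None and Zt.profile_kind != BINARY:
            keep = [b for b in shared if b in st.mean.index]
            sub_st = type(st)(st.mean.loc[keep], st.sd.loc[keep], st.dropped)
            Ze, _ = standardize_profile(Ze, sub_st)
            Zt_sub = Zt_sub.subset_biomarkers(keep)
            if Ze.values.isna().any().any():
                Ze = OmicMatrix(Ze.values.fillna(0.0), Ze.profile_kind, Ze.profile_name)
        processed.append(Ze)
        train_sub.append(Zt_sub)
    # cross-kernel on the intersected biomarker sets, training block at full size
    n_v = processed[0].n_subjects
    K_VT = np.zeros((n_v, len(model.subject_ids)))
    for s2, Ze, Zt in zip(results.sigma2_hat.to_numpy(), processed, train_sub):
        K_VT += s2 * (Ze.values.to_numpy(float) @ Zt.values.to_numpy(float).T) / Zt.n_biomarkers
    g_v = results.predict_g(K_VT)
    if len(results.beta_hat):
        b_v = external.clinical.values.loc[:, results.beta_hat.index].to_numpy(float) @ results.beta_hat.to_numpy()
    else:
        b_v = np.zeros(n_v)
    c = concordance_index(external.outcome, b_v + g_v)
    return c, report


@dataclass
class DownsampleGrid:
    """Mean C-index as a function of subject or biomarker count."""

    axis: str  # "subjects" or "biomarkers"
    sizes: list
    means: list
    repetitions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "mean_cindex": self.means})


def _kfold_cv(dataset, method, folds: int, seed: int) -> float:
    """Average validation C over a k-fold partition of the subjects."""
    ids = np.asarray(dataset.outcome.subject_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    splits = np.array_split(perm, folds)
    cs = []
    for f in range(folds):
        va_idx = splits[f]
        tr_idx = np.concatenate([splits[j] for j in range(folds) if j != f])
        va_ids, tr_ids = list(ids[va_idx]), list(ids[tr_idx])
        va_outcome = dataset.outcome.subset_subjects(va_ids)
        if va_outcome.n_events == 0:
            continue
        method.fit(*_split_dataset(dataset, tr_ids))
        va = _split_dataset(dataset, va_ids)
        cs.append(concordance_index(va_outcome, method.score(va[1], va[2])))
    if not cs:
        raise ValueError("every fold had an event-free validation part")
    return float(np.mean(cs))


def downsample_experiment(
    dataset,
    axis: str,
    sizes: Sequence[int],
    repetitions: int = 50,
    inner_cv_folds: int = 5,
    base_seed: int = 0,
    method_factory=None,
) -> DownsampleGrid:
    """How prognostic performance degrades with fewer subjects or biomarkers.

    For each size, subjects (keeping all biomarkers) or biomarkers
    (keeping all subjects) are sampled without replacement, the kernel
    method is evaluated by ``inner_cv_folds``-fold cross-validation, and
    the procedure repeats ``repetitions`` times; the per-size mean C-index
    is recorded.
    """
    if axis not in ("subjects", "biomarkers"):
        raise ValueError("axis must be 'subjects' or 'biomarkers'")
    sizes = list(sizes)
    if any(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly decreasing")
    if method_factory is None:
        method_factory = lambda: KernelMethod()  # noqa: E731
    ids = np.asarray(dataset.outcome.subject_ids)
    n = len(ids)
    p = dataset.profiles[0].n_biomarkers
    limit = n if axis == "subjects" else p
    if max(sizes) > limit:
        raise ValueError(f"size {max(sizes)} exceeds available {limit}")

    means = []
    for si, size in enumerate(sizes):
        vals = []
        for r in range(repetitions):
            seed = base_seed + 1000 * si + r
            rng = np.random.default_rng(seed)
            if axis == "subjects":
                keep = list(ids[np.sort(rng.choice(n, size, replace=False))])
                sub = _Subset(*_split_dataset(dataset, keep))
            else:
                cols = dataset.profiles[0].biomarker_ids
                keep_b = [cols[j] for j in np.sort(rng.choice(p, size, replace=False))]
                profiles = [dataset.profiles[0].subset_biomarkers(keep_b)] + list(
                    dataset.profiles[1:]
                )
                sub = _Subset(dataset.outcome, dataset.clinical, profiles)
            vals.append(_kfold_cv(sub, method_factory(), inner_cv_folds, seed))
        means.append(float(np.mean(vals)))
    return DownsampleGrid(axis=axis, sizes=sizes, means=means, repetitions=repetitions)


@dataclass
class _Subset:
    outcome: SurvivalOutcome
    clinical: object
    profiles: list


def cv_results_to_table(results: Sequence[CVResult], cohort: str) -> CIndexTable:
    """Summarize CV results of one cohort into meta-analysis records."""
    rows = [
        {"cohort": cohort, "method": r.method, "cindex": r.mean} for r in results
    ]
    return CIndexTable(pd.DataFrame(rows))
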