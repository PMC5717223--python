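"""Cross-cohort meta-analysis of prognostic performance.

C-indices of different predictors evaluated in the same cohort are
correlated: the cohort (cancer type) itself drives much of the variation.
The random-intercept linear mixed model

    y_ij = x_ij' beta + delta_i + eps_ij,
    delta_i ~ N(0, sigma_b^2),  eps_ij ~ N(0, sigma_eps^2),

treats the C-index y_ij of predictor j in cohort i as a repeated
prognosis evaluation of that cohort.  The share of variance explained by
cohort identity, S = sigma_b^2 / (sigma_b^2 + sigma_eps^2), is the
inter-profile heterogeneity: S = 1 means every predictor scores the same
within a cohort, S = 0 means the cohort contributes nothing.

Estimation is REML with the fixed effects and the residual variance
profiled out, leaving a one-dimensional search over the variance ratio
lambda = sigma_b^2 / sigma_eps^2.  Because the one-way covariance has a
closed-form inverse per cohort, the profiled criterion is exact, and on
balanced designs the interior optimum coincides with the classical
ANOVA method-of-moments solution.  Wald tests for fixed effects use the
normal reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CIndexTable",
    "VarianceDecomposition",
    "RandomInterceptLMM",
    "RandomInterceptResults",
    "fit_random_intercept",
    "compare_clinical_vs_omic",
    "compare_profiles",
    "compare_combination_vs_single",
    "compare_signatures_vs_kernel",
]

_LOG_LAM_LO, _LOG_LAM_HI = np.log(1e-10), np.log(1e10)


@dataclass
class CIndexTable:
    """Long-format (cohort, method, cindex) records."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cohort", "method", "cindex"}
        if not required.issubset(self.records.columns):
            raise ValueError("records need columns cohort, method, cindex")
        y = self.records["cindex"]
        if ((y < 0) | (y > 1)).any():
            raise ValueError("C-indices must lie in [0, 1]")
        if self.records.duplicated(["cohort", "method"]).any():
            raise ValueError("duplicate (cohort, method) pairs")

    @property
    def cohorts(self) -> list:
        return sorted(self.records["cohort"].unique())

    @property
    def methods(self) -> list:
        return sorted(self.records["method"].unique())

    def subset(self, methods: Sequence[str]) -> "CIndexTable":
        sub = self.records[self.records["method"].isin(methods)]
        return CIndexTable(sub.reset_index(drop=True))


@dataclass
class VarianceDecomposition:
    """Variance components of the random-intercept model and S."""

    beta0: float
    sigma_b2: float
    sigma_eps2: float
    at_boundary: bool = False

    @property
    def S(self) -> float:
        tot = self.sigma_b2 + self.sigma_eps2
        return self.sigma_b2 / tot if tot > 0 else 0.0


def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sums needed for the closed-form one-way GLS."""
    uniq, gidx = np.unique(groups, return_inverse=True)
    I = len(uniq)
    n_i = np.bincount(gidx, minlength=I).astype(float)
    p = X.shape[1]
    Xs = np.zeros((I, p))
    ys = np.zeros(I)
    for j in range(p):
        Xs[:, j] = np.bincount(gidx, weights=X[:, j], minlength=I)
    ys = np.bincount(gidx, weights=y, minlength=I)
    return n_i, Xs, ys


class RandomInterceptLMM:
    """Random-intercept linear mixed model for C-index tables.

    Parameters
    ----------
    endog : array-like
        Response values y_ij (C-indices).
    exog : DataFrame or array
        Fixed-effect design, intercept included.
    groups : array-like
        Cohort labels defining the random intercepts.
    """

    def __init__(self, endog, exog, groups) -> None:
        self.y = np.asarray(endog, float)
        if isinstance(exog, pd.DataFrame):
            self.xnames = list(exog.columns)
            self.X = exog.to_numpy(float)
        else:
            self.X = np.atleast_2d(np.asarray(exog, float))
            self.xnames = [f"x{j}" for j in range(self.X.shape[1])]
        self.groups = np.asarray(groups)
        if len(np.unique(self.groups)) < 2:
            raise ValueError("sigma_b^2 is unidentified with a single cohort")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        self._n_i, self._Xs, self._ys = _group_stats(self.X, self.y, self.groups)
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)

    def _gls(self, lam: float):
        """GLS quantities at variance ratio lam, using the one-way inverse
        V0_i^{-1} = I - (lam / (1 + n_i lam)) J."""
        c = lam / (1.0 + self._n_i * lam)
        XtVX = self._XtX - (self._Xs.T * c) @ self._Xs
        XtVy = self._Xty - self._Xs.T @ (c * self._ys)
        yVy = self._yty - float(c @ self._ys**2)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(yVy - float(beta @ XtVy), 1e-300)
        return beta, rss, XtVX

    def _neg_reml(self, log_lam: float) -> float:
        lam = np.exp(log_lam)
        N, p = self.X.shape
        beta, rss, XtVX = self._gls(lam)
        sign, ld = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e10
        return (
            (N - p) * np.log(rss / (N - p))
            + float(np.sum(np.log1p(self._n_i * lam)))
            + ld
        )

    def fit(self) -> "RandomInterceptResults":
        res = optimize.minimize_scalar(
            self._neg_reml,
            bounds=(_LOG_LAM_LO, _LOG_LAM_HI),
            method="bounded",
            options={"xatol": 1e-12},
        )
        lam = float(np.exp(res.x))
        at_boundary = False
        # compare against the lambda = 0 boundary (no cohort effect)
        if self._neg_reml(_LOG_LAM_LO) <= res.fun + 1e-10:
            lam = 0.0
            at_boundary = True
        beta, rss, XtVX = self._gls(lam)
        N, p = self.X.shape
        sigma_eps2 = rss / (N - p)
        sigma_b2 = lam * sigma_eps2
        cov = sigma_eps2 * np.linalg.inv(XtVX)
        return RandomInterceptResults(
            model=self,
            params=pd.Series(beta, index=self.xnames),
            cov_params=pd.DataFrame(cov, index=self.xnames, columns=self.xnames),
            variance=VarianceDecomposition(
                beta0=float(beta[0]),
                sigma_b2=float(sigma_b2),
                sigma_eps2=float(sigma_eps2),
                at_boundary=at_boundary,
            ),
            reml_criterion=float(res.fun),
        )


@dataclass
class RandomInterceptResults:
    """REML fit: fixed effects, their covariance, and variance components."""

    model: RandomInterceptLMM
    params: pd.Series
    cov_params: pd.DataFrame
    variance: VarianceDecomposition
    reml_criterion: float

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    def contrast(self, L: np.ndarray) -> tuple[float, float, float]:
        """Estimate, SE and Wald p of a linear combination L' beta."""
        L = np.asarray(L, float)
        est = float(L @ self.params.to_numpy())
        se = float(np.sqrt(L @ self.cov_params.to_numpy() @ L))
        p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
        return est, se, p

    def summary(self) -> str:
        v = self.variance
        lines = [
            "Random-intercept linear mixed model (REML)",
            "=" * 60,
            f"observations: {len(self.model.y)}    "
            f"cohorts: {len(np.unique(self.model.groups))}",
            f"sigma_b^2 = {v.sigma_b2:.6f}    sigma_eps^2 = {v.sigma_eps2:.6f}",
            f"inter-profile heterogeneity S = {v.S:.4f}"
            + ("    (boundary: sigma_b^2 = 0)" if v.at_boundary else ""),
            "",
            f"{'term':<22s}{'estimate':>10s}{'se':>10s}{'z':>8s}{'p':>10s}",
            "-" * 60,
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22s}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.zvalues[name]:>8.2f}{self.pvalues[name]:>10.2g}"
            )
        return "\n".join(lines)


def _check_table(table: CIndexTable, min_cohorts: int = 3) -> None:
    if len(table.cohorts) < min_cohorts:
        raise ValueError(f"need at least {min_cohorts} cohorts")


def fit_random_intercept(
    table: CIndexTable, design: Optional[pd.DataFrame] = None
) -> RandomInterceptResults:
    """Fit y_ij = x' beta + delta_i + eps_ij; intercept-only by default.

    ``design`` supplies extra fixed-effect indicator columns aligned with
    ``table.records``; an intercept is always prepended.
    """
    _check_table(table)
    rec = table.records
    X = pd.DataFrame({"intercept": np.ones(len(rec))}, index=rec.index)
    if design is not None:
        X = pd.concat([X, design.set_axis(rec.index)], axis=1)
    return RandomInterceptLMM(rec["cindex"], X, rec["cohort"]).fit()


def compare_clinical_vs_omic(
    table: CIndexTable, clinical_labels: Sequence[str] = ("clinical",)
) -> RandomInterceptResults:
    """Clinical-vs-omic contrast: indicator = 1 for clinical-variable rows."""
    rec = table.records
    x = rec["method"].isin(clinical_labels).astype(float)
    if x.sum() == 0 or x.sum() == len(x):
        raise ValueError("table must contain both clinical and omic rows")
    return fit_random_intercept(table, pd.DataFrame({"clinical": x}))


def compare_profiles(
    table: CIndexTable, profiles: Optional[Sequence[str]] = None
) -> tuple[RandomInterceptResults, pd.DataFrame]:
    """Per-profile deviation from the average prognostic power.

    Sum-to-zero (effect) coding makes each coefficient the deviation of
    that profile's mean C-index from the across-profile average; the last
    profile's deviation is recovered as minus the sum, with its SE from
    the corresponding contrast.  Returns the fit and a table of
    (profile, deviation, se, p).
    """
    if profiles is None:
        profiles = table.methods
    counts = table.records.groupby("method")["cohort"].nunique()
    kept = [p for p in profiles if counts.get(p, 0) >= 2]
    dropped = sorted(set(profiles) - set(kept))
    if dropped:
        warnings.warn(f"profiles present in <2 cohorts dropped: {dropped}")
    if len(kept) < 2:
        raise ValueError("need at least two profiles across cohorts")
    sub = table.subset(kept)
    rec = sub.records
    K = len(kept)
    design = pd.DataFrame(0.0, index=rec.index, columns=kept[:-1])
    for k, prof in enumerate(kept[:-1]):
        design.loc[rec["method"] == prof, prof] = 1.0
    design.loc[rec["method"] == kept[-1], :] = -1.0
    res = fit_random_intercept(sub, design)
    rows = []
    for prof in kept[:-1]:
        rows.append((prof, res.params[prof], res.bse[prof], res.pvalues[prof]))
    L = np.zeros(K)  # intercept + K-1 coded terms
    L[1:] = -1.0
    est, se, p = res.contrast(L)
    rows.append((kept[-1], est, se, p))
    dev = pd.DataFrame(rows, columns=["profile", "deviation", "se", "p"]).set_index("profile")
    return res, dev


def compare_combination_vs_single(
    table: CIndexTable, combination_labels: Optional[Sequence[str]] = None
) -> RandomInterceptResults:
    """Two-profile-combination vs single-profile contrast.

    By default a method label containing '+' marks a pairwise kernel
    combination.
    """
    rec = table.records
    if combination_labels is None:
        combination_labels = [m for m in table.methods if "+" in m]
    z = rec["method"].isin(combination_labels).astype(float)
    if z.sum() == 0 or z.sum() == len(z):
        raise ValueError("table must contain both combination and single-profile rows")
    return fit_random_intercept(table, pd.DataFrame({"combination": z}))


def compare_signatures_vs_kernel(
    table: CIndexTable,
    kernel_label: str,
    signature_labels: Sequence[str],
) -> RandomInterceptResults:
    """Signature methods (Lasso, metagene, immune, ...) vs the full-profile
    kernel method, one indicator per signature; kernel rows are baseline."""
    rec = table.records
    present = set(rec["method"])
    missing = [s for s in signature_labels if s not in present]
    if kernel_label not in present:
        raise ValueError(f"kernel arm {kernel_label!r} absent from table")
    if missing:
        raise ValueError(f"signature arms absent from table: {missing}")
    keep = [kernel_label, *signature_labels]
    sub = table.subset(keep)
    rec = sub.records
    design = pd.DataFrame(0.0, index=rec.index, columns=list(signature_labels))
    for s in signature_labels:
        design.loc[rec["method"] == s, s] = 1.0
    return fit_random_intercept(sub, design)
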