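"""Kernel-fusion Cox proportional hazards model.

The hazard of subject i is lambda_i(t) = lambda_0(t) exp(eta_i) with an
overall prognostic score eta_i = b_i + g_i: a clinical part b = X beta
(fixed effects) and an omic part g, a random prognostic score with prior
g ~ N(0, K) where K = sum_m sigma2_m K_m fuses the per-profile similarity
kernels.  Equivalently g_m = Z_m alpha_m with i.i.d. random biomarker
coefficients alpha_mj ~ N(0, sigma2_m / p_m) — the kernel form lets the
model aggregate tens of thousands of biomarkers at once.

Fitting proceeds in two nested loops.  For fixed variance components the
penalized partial likelihood l_cox(X beta + g) - g' K^{-1} g / 2 is
maximized over (beta, g) by Newton iterations with step halving.  The
variance components themselves maximize a Laplace approximation of the
integrated partial likelihood,

    l(sigma2) = PPL(beta_hat, g_hat) - log det(I + K W) / 2,

with W the negative curvature of the Cox log-likelihood at the optimum,
optimized derivative-free on the log scale within a box.  Prediction for
new subjects is the best linear unbiased predictor
g_V = K_VT K_TT^{-1} g_T built from the cross-kernel between validation
and training subjects.

The baseline hazard is never estimated: all outputs are relative risk
scores, which is what the rank-based concordance index consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ClinicalTable, OmicMatrix, StandardizationStats, SurvivalOutcome
from .kernels import Kernel, build_linear_kernel, fuse_kernels

__all__ = [
    "cox_partial_loglik",
    "fit_ppl",
    "blup_predict",
    "KernelCoxPH",
    "KernelCoxPHResults",
    "PredictionResult",
    "PPLFit",
]

SIGMA2_FLOOR = 1e-6
SIGMA2_CEIL = 1e3


def cox_partial_loglik(eta: np.ndarray, outcome: SurvivalOutcome):
    """Breslow-ties Cox log partial likelihood with gradient and Hessian.

    Returns ``(value, grad, hess)`` as functions of the linear predictor
    eta.  The Hessian is the exact negative-semidefinite curvature
    -sum_t d_t (diag(pi_t) - pi_t pi_t'), computed in O(n^2).
    """
    eta = np.asarray(eta, float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite values in eta")
    time, event = outcome.time, outcome.event
    if event.sum() == 0:
        raise ValueError("no events in outcome")
    n = len(eta)
    order = np.argsort(-time, kind="stable")  # descending time
    t_s, ev_s, eta_s = time[order], event[order], eta[order]
    shift = float(eta_s.max())  # value/grad/hess are shift-invariant in eta
    e = np.exp(eta_s - shift)
    cum = np.cumsum(e)

    # distinct event times, risk set = prefix of the descending order
    ev_times = np.unique(t_s[ev_s == 1])[::-1]
    # L[q]: number of subjects with time >= ev_times[q]
    L = np.searchsorted(-t_s, -ev_times, side="right")
    d = np.array([np.sum((t_s == t) & (ev_s == 1)) for t in ev_times], float)
    # floor guards against underflow of shifted risk-set sums when eta is
    # pathologically spread out (separation); harmless otherwise
    S = np.maximum(cum[L - 1], 1e-120)

    loglik = float(np.sum(eta_s[ev_s == 1]) - np.sum(d * (np.log(S) + shift)))

    contrib_a = np.zeros(n)
    contrib_c = np.zeros(n)
    np.add.at(contrib_a, L - 1, d / S)
    np.add.at(contrib_c, L - 1, d / S**2)
    a = np.cumsum(contrib_a[::-1])[::-1]  # a_k = sum over events whose risk set covers k
    c = np.cumsum(contrib_c[::-1])[::-1]

    grad_s = ev_s - e * a
    idx = np.arange(n)
    H_s = np.outer(e, e) * c[np.maximum.outer(idx, idx)]
    H_s[idx, idx] -= e * a

    inv = np.empty(n, int)
    inv[order] = idx
    grad = grad_s[inv]
    hess = H_s[np.ix_(inv, inv)]
    return loglik, grad, hess


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] == 0:
        return
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _kernel_inverse(K: np.ndarray, jitter: float):
    """Eigendecomposition-based inverse with a floor on near-zero eigenvalues."""
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    w = np.maximum(w, jitter)
    Kinv = (V / w) @ V.T
    return Kinv, w, V


@dataclass
class PPLFit:
    """Inner-loop solution (beta, g) of the penalized partial likelihood."""

    beta: np.ndarray
    g: np.ndarray
    loglik_cox: float
    penalized_objective: float
    iterations: int
    gradient_norm: float
    objective_trace: list = field(default_factory=list)
    hess_eta: Optional[np.ndarray] = None
    neg_hess_full: Optional[np.ndarray] = None


def fit_ppl(
    outcome: SurvivalOutcome,
    X: Optional[np.ndarray],
    K: np.ndarray,
    jitter: Optional[float] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    covariate_names: Optional[Sequence[str]] = None,
    start: Optional[tuple] = None,
) -> PPLFit:
    """Maximize l_cox(X beta + g) - g' K~^{-1} g / 2 for a fixed fused kernel.

    Newton iterations in the joint (beta, g) vector with step halving; the
    kernel is inverted through its eigendecomposition with eigenvalues
    floored at the jitter (default 1e-8 times the mean kernel diagonal),
    which keeps rank-deficient kernels (p_m < n, duplicated subjects)
    well posed.
    """
    n = len(outcome.subject_ids)
    if X is None:
        X = np.zeros((n, 0))
    X = np.asarray(X, float)
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(X.shape[1])]
    _check_full_rank(X, covariate_names)
    q = X.shape[1]
    if jitter is None:
        md = float(np.mean(np.diag(K)))
        jitter = 1e-8 * (md if md > 0 else 1.0)
    Kinv, _, _ = _kernel_inverse(K, jitter)

    if start is not None:
        beta, g = start[0].copy(), start[1].copy()
    else:
        beta, g = np.zeros(q), np.zeros(n)

    def objective(beta, g):
        eta = X @ beta + g
        ll, grad_eta, hess_eta = cox_partial_loglik(eta, outcome)
        pen = ll - 0.5 * g @ Kinv @ g
        return pen, ll, grad_eta, hess_eta

    pen, ll, grad_eta, hess_eta = objective(beta, g)
    trace = [pen]
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        grad = np.concatenate([X.T @ grad_eta, grad_eta - Kinv @ g])
        grad_norm = float(np.linalg.norm(grad, ord=np.inf))
        if grad_norm < tol:
            break
        # negative Hessian of the penalized objective (positive definite in g)
        A = np.empty((q + n, q + n))
        XtH = X.T @ hess_eta
        A[:q, :q] = -XtH @ X
        A[:q, q:] = -XtH
        A[q:, :q] = -XtH.T
        A[q:, q:] = -hess_eta + Kinv
        A[np.diag_indices_from(A)] += 1e-12
        try:
            step = np.linalg.solve(A, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            nb = beta + scale * step[:q]
            ng = g + scale * step[q:]
            new_pen, new_ll, new_grad_eta, new_hess_eta = objective(nb, ng)
            if new_pen >= pen - 1e-12:
                break
            scale *= 0.5
        else:
            break  # no ascent possible: at numerical optimum
        beta, g = nb, ng
        pen, ll, grad_eta, hess_eta = new_pen, new_ll, new_grad_eta, new_hess_eta
        trace.append(pen)
    else:
        if grad_norm >= max(tol, 1e-4):
            raise RuntimeError(
                f"penalized partial likelihood did not converge in {max_iter} "
                f"iterations (gradient norm {grad_norm:.2e}); trace={trace}"
            )

    A = np.empty((q + n, q + n))
    XtH = X.T @ hess_eta
    A[:q, :q] = -XtH @ X
    A[:q, q:] = -XtH
    A[q:, :q] = -XtH.T
    A[q:, q:] = -hess_eta + Kinv
    return PPLFit(
        beta=beta,
        g=g,
        loglik_cox=ll,
        penalized_objective=pen,
        iterations=it,
        gradient_norm=grad_norm,
        objective_trace=trace,
        hess_eta=hess_eta,
        neg_hess_full=A,
    )


def blup_predict(
    g_train: np.ndarray, K_VT: np.ndarray, K_TT: np.ndarray, jitter: Optional[float] = None
) -> np.ndarray:
    """Best linear unbiased predictor g_V = K_VT (K_TT + delta I)^{-1} g_T."""
    g_train = np.asarray(g_train, float)
    K_VT = np.atleast_2d(np.asarray(K_VT, float))
    K_TT = np.asarray(K_TT, float)
    if K_VT.shape[1] != K_TT.shape[0] or K_TT.shape[0] != len(g_train):
        raise ValueError(
            f"dimension mismatch: K_VT {K_VT.shape}, K_TT {K_TT.shape}, "
            f"g_T {g_train.shape}"
        )
    if jitter is None:
        md = float(np.mean(np.diag(K_TT)))
        jitter = 1e-8 * (md if md > 0 else 1.0)
    Kinv, _, _ = _kernel_inverse(K_TT, jitter)
    return K_VT @ (Kinv @ g_train)


@dataclass
class PredictionResult:
    """Predicted clinical (b), omic (g) and overall (eta = b + g) scores."""

    subject_ids: list
    b_v: np.ndarray
    g_v: np.ndarray

    @property
    def eta_v(self) -> np.ndarray:
        return self.b_v + self.g_v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"b": self.b_v, "g": self.g_v, "eta": self.eta_v}, index=self.subject_ids
        )


class KernelCoxPH:
    """Kernel-fusion Cox model for multi-omic survival prognosis.

    Parameters
    ----------
    outcome : SurvivalOutcome
        Right-censored survival times with at least one event.
    profiles : sequence of OmicMatrix
        Preprocessed training profiles (continuous ones standardized,
        binary ones raw 0/1); one linear kernel is built per profile.
    clinical : ClinicalTable, optional
        Fixed-effect covariates (no intercept — the Cox partial
        likelihood absorbs it into the baseline).
    kernels : sequence of Kernel, optional
        Pre-built kernels may be supplied instead of ``profiles``.
    stats : dict, optional
        Per-profile StandardizationStats recorded for later application
        to validation data.

    By default at most two kernels are fused (single profiles and their
    pairwise combinations); pass ``allow_many=True`` to lift the cap.
    """

    def __init__(
        self,
        outcome: SurvivalOutcome,
        profiles: Optional[Sequence[OmicMatrix]] = None,
        clinical: Optional[ClinicalTable] = None,
        kernels: Optional[Sequence[Kernel]] = None,
        stats: Optional[dict] = None,
        allow_many: bool = False,
    ) -> None:
        if (profiles is None) == (kernels is None):
            raise ValueError("supply exactly one of profiles= or kernels=")
        self.outcome = outcome
        self.subject_ids = outcome.subject_ids
        self.clinical = clinical
        self.profiles = list(profiles) if profiles is not None else None
        if kernels is None:
            kernels = [build_linear_kernel(Z) for Z in self.profiles]
        self.kernels = list(kernels)
        if not (1 <= len(self.kernels) <= 3) and not allow_many:
            raise ValueError("1-3 kernels supported (pass allow_many=True to override)")
        for k in self.kernels:
            if k.subject_ids != self.subject_ids:
                raise ValueError(
                    f"kernel {k.source_profile!r} subjects differ from the outcome"
                )
        if clinical is not None and clinical.subject_ids != self.subject_ids:
            raise ValueError("clinical table subjects differ from the outcome")
        self.stats = stats or {}
        self._K_arrays = [k.to_numpy() for k in self.kernels]
        self._X = clinical.values.to_numpy(float) if clinical is not None else None
        self._xnames = clinical.covariate_names if clinical is not None else []

    # -- fitting ----------------------------------------------------------

    def _fused(self, sigma2: np.ndarray) -> np.ndarray:
        K = np.zeros_like(self._K_arrays[0])
        for s, Km in zip(sigma2, self._K_arrays):
            K += s * Km
        return K

    def laplace_criterion(self, sigma2: Sequence[float], start=None):
        """Laplace-approximated integrated partial likelihood at sigma2."""
        sigma2 = np.asarray(sigma2, float)
        K = self._fused(sigma2)
        md = float(np.mean(np.diag(K)))
        jitter = 1e-8 * (md if md > 0 else 1.0)
        Kt = K + jitter * np.eye(K.shape[0])
        fit = fit_ppl(
            self.outcome, self._X, Kt, jitter=jitter,
            covariate_names=self._xnames, start=start,
        )
        W = -fit.hess_eta
        sign, logdet = np.linalg.slogdet(np.eye(K.shape[0]) + Kt @ W)
        if sign <= 0:
            raise RuntimeError("non-positive determinant in Laplace criterion")
        return fit.penalized_objective - 0.5 * logdet, fit

    def fit(
        self,
        sigma2: Optional[Sequence[float]] = None,
        outer_tol: float = 1e-4,
        max_outer_evals: int = 100,
    ) -> "KernelCoxPHResults":
        """Estimate variance components (unless fixed) and fit the model.

        With ``sigma2`` given the outer optimization is skipped and only
        the penalized partial likelihood is solved at those variance
        components.
        """
        M = len(self.kernels)
        if sigma2 is not None:
            sigma2 = np.asarray(sigma2, float)
            crit, fit = self.laplace_criterion(sigma2)
            return self._package(sigma2, fit, crit, n_outer=0, no_signal=False)

        warm = {"start": None}

        def neg_crit(log_s2):
            s2 = np.exp(np.clip(log_s2, np.log(SIGMA2_FLOOR), np.log(SIGMA2_CEIL)))
            try:
                crit, fit = self.laplace_criterion(s2, start=warm["start"])
            except (RuntimeError, np.linalg.LinAlgError):
                return 1e10
            warm["start"] = (fit.beta, fit.g)
            return -crit

        x0 = np.log(np.full(M, 0.5))
        bounds = [(np.log(SIGMA2_FLOOR), np.log(SIGMA2_CEIL))] * M
        res = optimize.minimize(
            neg_crit,
            x0,
            method="Powell",
            bounds=bounds,
            options={"ftol": outer_tol, "xtol": 1e-3, "maxfev": max_outer_evals},
        )
        s2_hat = np.exp(np.clip(res.x, np.log(SIGMA2_FLOOR), np.log(SIGMA2_CEIL)))
        crit, fit = self.laplace_criterion(s2_hat)
        no_signal = bool(np.all(s2_hat <= SIGMA2_FLOOR * 10))
        return self._package(s2_hat, fit, crit, n_outer=int(res.nfev), no_signal=no_signal)

    def _package(self, sigma2, fit: PPLFit, criterion, n_outer, no_signal):
        return KernelCoxPHResults(
            model=self,
            sigma2_hat=pd.Series(sigma2, index=[k.source_profile for k in self.kernels]),
            beta_hat=pd.Series(fit.beta, index=self._xnames),
            g_hat=pd.Series(fit.g, index=self.subject_ids),
            inner_fit=fit,
            criterion=float(criterion),
            n_outer_evals=n_outer,
            no_signal=no_signal,
        )


@dataclass
class KernelCoxPHResults:
    """Fitted kernel-fusion Cox model.

    Carries the fixed-effect estimates, the variance components of each
    omic kernel, the training BLUPs, and enough of the training data to
    score new subjects.
    """

    model: KernelCoxPH
    sigma2_hat: pd.Series
    beta_hat: pd.Series
    g_hat: pd.Series
    inner_fit: PPLFit
    criterion: float
    n_outer_evals: int
    no_signal: bool

    @property
    def eta_train(self) -> pd.Series:
        X = self.model._X
        b = X @ self.beta_hat.to_numpy() if X is not None else 0.0
        return pd.Series(b + self.g_hat.to_numpy(), index=self.model.subject_ids)

    def bse(self) -> pd.Series:
        """Standard errors of the fixed effects from the penalized curvature."""
        q = len(self.beta_hat)
        if q == 0:
            return pd.Series(dtype=float)
        cov = np.linalg.inv(self.inner_fit.neg_hess_full)[:q, :q]
        return pd.Series(np.sqrt(np.diag(cov)), index=self.beta_hat.index)

    # -- prediction -------------------------------------------------------

    def predict_g(self, K_VT: np.ndarray, K_TT: Optional[np.ndarray] = None) -> np.ndarray:
        """BLUP of omic prognostic scores from explicit kernel blocks."""
        if K_TT is None:
            K_TT = self.model._fused(self.sigma2_hat.to_numpy())
        return blup_predict(self.g_hat.to_numpy(), K_VT, K_TT)

    def predict(
        self,
        clinical: Optional[ClinicalTable] = None,
        profiles: Optional[Sequence[OmicMatrix]] = None,
    ) -> PredictionResult:
        """Overall prognostic scores eta_V = b_V + g_V for new subjects.

        ``profiles`` must be preprocessed with the training
        StandardizationStats (use :func:`kernsurv.io.standardize_profile`
        with the stored stats) and ordered like the training profiles.
        """
        if profiles is None and any(self.sigma2_hat > SIGMA2_FLOOR * 10):
            if self.model.profiles is None:
                raise ValueError("model built from kernels; supply cross-kernel via predict_g")
        # clinical part
        if len(self.beta_hat):
            if clinical is None:
                raise ValueError("model has fixed effects; clinical table required")
            missing = set(self.beta_hat.index) - set(clinical.values.columns)
            if missing:
                raise ValueError(f"validation clinical table lacks covariates {sorted(missing)}")
            Xv = clinical.values.loc[:, self.beta_hat.index].to_numpy(float)
            b_v = Xv @ self.beta_hat.to_numpy()
            ids = clinical.subject_ids
        else:
            b_v = None
            ids = None

        # omic part
        if profiles is not None:
            if self.model.profiles is None:
                raise ValueError("model was built from kernels, not profiles")
            if len(profiles) != len(self.model.profiles):
                raise ValueError("one validation profile per training profile required")
            n_v = profiles[0].n_subjects
            K_VT = np.zeros((n_v, len(self.model.subject_ids)))
            for s2, Zv, Zt in zip(self.sigma2_hat.to_numpy(), profiles, self.model.profiles):
                if Zv.biomarker_ids != Zt.biomarker_ids:
                    raise ValueError(
                        f"validation profile {Zv.profile_name!r} biomarkers differ "
                        "from training"
                    )
                K_VT += s2 * (Zv.values.to_numpy(float) @ Zt.values.to_numpy(float).T) / Zt.n_biomarkers
            g_v = self.predict_g(K_VT)
            if ids is None:
                ids = profiles[0].subject_ids
            elif profiles[0].subject_ids != ids:
                raise ValueError("clinical and omic validation subjects differ")
        else:
            g_v = np.zeros(len(ids)) if ids is not None else None
        if ids is None:
            raise ValueError("nothing to predict from: supply clinical and/or profiles")
        if b_v is None:
            b_v = np.zeros(len(ids))
        return PredictionResult(subject_ids=list(ids), b_v=b_v, g_v=g_v)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Kernel-fusion Cox model",
            "=" * 58,
            f"subjects: {len(self.model.subject_ids)}    "
            f"events: {self.model.outcome.n_events}",
            f"Laplace criterion: {self.criterion:.4f}    "
            f"inner iterations: {self.inner_fit.iterations}    "
            f"outer evaluations: {self.n_outer_evals}",
            "",
            "Variance components (sigma^2 per omic kernel)",
            "-" * 58,
        ]
        for name, val in self.sigma2_hat.items():
            flag = "  (at lower bound: no omic signal)" if val <= SIGMA2_FLOOR * 10 else ""
            lines.append(f"  {name:<24s} {val:>12.4f}{flag}")
        if len(self.beta_hat):
            lines += ["", "Fixed effects", "-" * 58]
            se = self.bse()
            for name in self.beta_hat.index:
                b = self.beta_hat[name]
                s = se[name]
                z = b / s if s > 0 else np.nan
                lines.append(f"  {name:<24s} {b:>10.4f}  se {s:>8.4f}  z {z:>7.2f}")
        g = self.g_hat.to_numpy()
        lines += [
            "",
            f"training BLUPs: mean {g.mean():+.4f}  sd {g.std():.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Portable serialization (JSON-friendly) of the fitted model."""
        return {
            "beta": self.beta_hat.to_dict(),
            "sigma2": self.sigma2_hat.to_dict(),
            "g_train": self.g_hat.to_dict(),
            "criterion": self.criterion,
            "no_signal": self.no_signal,
        }
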