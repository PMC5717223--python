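"""Synthetic multi-omic survival cohorts.

The generator draws data from exactly the random-coefficient structure
the kernel-fusion Cox model assumes: per-profile biomarker effects
alpha_mj ~ N(0, sigma2_m / p_m), omic prognostic scores g_m = Z_m alpha_m,
clinical fixed effects b = X beta, and event times from a proportional
hazards model with a constant (exponential) baseline hazard,
T_i ~ Exp(rate = lambda_0 exp(eta_i)).  Censoring is an independent
exponential whose rate is calibrated numerically so the realized censored
fraction matches the target.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io import BINARY, CONTINUOUS, ClinicalTable, OmicMatrix, SurvivalOutcome
from .meta import CIndexTable

__all__ = ["ProfileSpec", "SyntheticDataset", "generate_cohort", "generate_cindex_table"]


@dataclass
class ProfileSpec:
    """Configuration of one simulated omic profile."""

    name: str
    p: int
    kind: str = CONTINUOUS
    sigma2: float = 1.0


@dataclass
class SyntheticDataset:
    """A generated cohort together with its ground truth."""

    profiles: list  # OmicMatrix, processed scale (continuous standardized)
    clinical: Optional[ClinicalTable]
    outcome: SurvivalOutcome
    alpha: dict  # profile name -> true random coefficients
    sigma2: dict  # profile name -> true variance component
    beta: np.ndarray  # true fixed effects
    b: np.ndarray
    g: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def eta(self) -> np.ndarray:
        return self.b + self.g

    @property
    def subject_ids(self) -> list:
        return self.outcome.subject_ids


def _calibrate_censoring(T: np.ndarray, target: float) -> float:
    """Rate of an independent exponential censor achieving the target fraction.

    The expected censored fraction at rate theta is
    mean_i(1 - exp(-theta T_i)); monotone in theta, so solved by bisection.
    """
    if not 0 <= target < 1:
        raise ValueError("censoring rate must lie in [0, 1)")
    if target == 0:
        return 0.0

    def frac(log_theta):
        return np.mean(1.0 - np.exp(-np.exp(log_theta) * T)) - target

    lo, hi = -30.0, 30.0
    if frac(lo) > 0 or frac(hi) < 0:
        raise ValueError("censoring calibration impossible for these event times")
    return float(np.exp(optimize.brentq(frac, lo, hi, xtol=1e-12)))


def generate_cohort(
    n: int,
    profiles: Sequence[ProfileSpec] = (ProfileSpec("mRNA", 300, CONTINUOUS, 1.0),),
    n_covariates: int = 2,
    beta: Optional[Sequence[float]] = None,
    baseline_rate: float = 0.1,
    censoring_rate: float = 0.3,
    seed: int = 0,
    mutation_rate_range: tuple = (0.001, 0.1),
) -> SyntheticDataset:
    """Simulate a multi-omic cohort with censored survival outcomes.

    Continuous profiles are drawn as independent standard-normal columns
    and column-standardized (population SD); binary profiles are Bernoulli
    with per-gene rates log-uniform in ``mutation_rate_range``, mimicking
    sparse somatic mutation patterns.  The prognostic score is
    eta = X beta + sum_m Z_m alpha_m with alpha_mj ~ N(0, sigma2_m / p_m).
    """
    if n < 10:
        raise ValueError("need n >= 10 subjects")
    rng = np.random.default_rng(seed)
    ids = [f"S{i:04d}" for i in range(n)]

    omics, alpha, sigma2 = [], {}, {}
    g = np.zeros(n)
    for spec in profiles:
        if spec.sigma2 < 0:
            raise ValueError("variance components must be nonnegative")
        if spec.kind == BINARY:
            lo, hi = np.log(mutation_rate_range[0]), np.log(mutation_rate_range[1])
            rates = np.exp(rng.uniform(lo, hi, size=spec.p))
            Z = (rng.random((n, spec.p)) < rates).astype(float)
        else:
            Z = rng.standard_normal((n, spec.p))
            mu = Z.mean(axis=0)
            sd = Z.std(axis=0, ddof=0)
            Z = (Z - mu) / sd
        a = rng.normal(0.0, np.sqrt(spec.sigma2 / spec.p), size=spec.p)
        g += Z @ a
        cols = [f"{spec.name}_g{j:05d}" for j in range(spec.p)]
        omics.append(
            OmicMatrix(pd.DataFrame(Z, index=ids, columns=cols), spec.kind, spec.name)
        )
        alpha[spec.name] = a
        sigma2[spec.name] = spec.sigma2

    if n_covariates > 0:
        X = rng.standard_normal((n, n_covariates))
        if beta is None:
            beta = np.zeros(n_covariates)
        beta = np.asarray(beta, float)
        if len(beta) != n_covariates:
            raise ValueError("beta length must equal n_covariates")
        b = X @ beta
        clinical = ClinicalTable(
            pd.DataFrame(X, index=ids, columns=[f"cov{j}" for j in range(n_covariates)])
        )
    else:
        beta = np.zeros(0)
        b = np.zeros(n)
        clinical = None

    eta = b + g
    T = rng.exponential(1.0 / (baseline_rate * np.exp(eta)))
    theta = _calibrate_censoring(T, censoring_rate)
    if theta > 0:
        C = rng.exponential(1.0 / theta, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, int)

    outcome = SurvivalOutcome(pd.DataFrame({"time": time, "event": event}, index=ids))
    return SyntheticDataset(
        profiles=omics,
        clinical=clinical,
        outcome=outcome,
        alpha=alpha,
        sigma2=sigma2,
        beta=beta,
        b=b,
        g=g,
        config={
            "n": n,
            "profiles": [(s.name, s.p, s.kind, s.sigma2) for s in profiles],
            "baseline_rate": baseline_rate,
            "censoring_rate": censoring_rate,
            "seed": seed,
        },
    )


def generate_cindex_table(
    n_cohorts: int,
    n_methods: int,
    beta0: float = 0.6,
    method_effects: Optional[Sequence[float]] = None,
    sigma_b2: float = 0.009,
    sigma_eps2: float = 0.003,
    seed: int = 0,
    method_labels: Optional[Sequence[str]] = None,
) -> CIndexTable:
    """Simulate a long-format cohort x method C-index table.

    y_ij = beta0 + effect_j + delta_i + eps_ij with cohort intercepts
    delta_i ~ N(0, sigma_b2) and residuals eps_ij ~ N(0, sigma_eps2);
    values are clipped to [0, 1] and generation fails if clipping affects
    more than 5% of cells (parameters unrealistic for a C-index).
    """
    if n_cohorts < 3 or n_methods < 2:
        raise ValueError("need at least 3 cohorts and 2 methods")
    rng = np.random.default_rng(seed)
    if method_effects is None:
        method_effects = np.zeros(n_methods)
    method_effects = np.asarray(method_effects, float)
    if method_labels is None:
        method_labels = [f"method{j + 1}" for j in range(n_methods)]
    delta = rng.normal(0.0, np.sqrt(sigma_b2), size=n_cohorts)
    eps = rng.normal(0.0, np.sqrt(sigma_eps2), size=(n_cohorts, n_methods))
    y = beta0 + method_effects[None, :] + delta[:, None] + eps
    clipped = int(np.sum((y < 0) | (y > 1)))
    if clipped > 0.05 * y.size:
        raise ValueError(
            f"{clipped}/{y.size} simulated C-indices fall outside [0, 1]; "
            "choose more realistic parameters"
        )
    y = np.clip(y, 0.0, 1.0)
    records = pd.DataFrame(
        {
            "cohort": np.repeat([f"cohort{i + 1}" for i in range(n_cohorts)], n_methods),
            "method": list(method_labels) * n_cohorts,
            "cindex": y.ravel(),
        }
    )
    return CIndexTable(records)
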