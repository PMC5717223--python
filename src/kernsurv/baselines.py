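"""Comparator prognostic predictors.

These are the established alternatives the kernel-fusion model is
benchmarked against: a clinical-covariates-only Cox model, an L1
(Lasso)-penalized Cox signature selected from one omic profile, fixed
gene-list (metagene-style) average-expression scores, a polygenic risk
score from externally reported SNP weights, and Cox models on externally
supplied signature scores or subtype labels.  Every comparator exposes
the same fit-on-training / score-validation interface so the Monte Carlo
cross-validation harness treats them interchangeably with the kernel
method.

Plain Cox estimation delegates to scikit-survival (Breslow ties, matching
the kernel model's convention); the L1 path delegates to scikit-survival's
Coxnet.  Immune, PAM50 and MammaPrint internals are never recomputed here
— they enter only as supplied scores, labels or gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .io import (
    BINARY,
    ClinicalTable,
    OmicMatrix,
    StandardizationStats,
    SurvivalOutcome,
    impute_and_filter,
    standardize_profile,
)
from .model import KernelCoxPH, cox_partial_loglik, _check_full_rank

__all__ = [
    "SignatureScore",
    "LassoSignature",
    "ClinicalCoxResults",
    "clinical_cox",
    "lasso_cox_signature",
    "genelist_score",
    "prs_score",
    "covariate_signature_cox",
    "ClinicalCoxMethod",
    "KernelMethod",
    "LassoMethod",
    "GeneListSignatureMethod",
]


@dataclass
class SignatureScore:
    """One scalar prognostic score per subject."""

    name: str
    scores: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(float))):
            raise ValueError(f"non-finite scores in signature {self.name!r}")

    @property
    def subject_ids(self) -> list:
        return list(self.scores.index)


@dataclass
class LassoSignature:
    """Biomarkers selected by the L1-penalized Cox path."""

    selected: list
    coefficients: pd.Series
    penalty: float
    seed: int
    empty: bool = False


@dataclass
class ClinicalCoxResults:
    """Plain Cox fit: coefficients, SEs and a linear risk scorer."""

    beta: pd.Series
    bse: pd.Series

    def risk(self, X: ClinicalTable | pd.DataFrame) -> np.ndarray:
        df = X.values if isinstance(X, ClinicalTable) else X
        missing = set(self.beta.index) - set(df.columns)
        if missing:
            raise ValueError(f"missing covariates: {sorted(missing)}")
        return df.loc[:, self.beta.index].to_numpy(float) @ self.beta.to_numpy()


def _surv_y(outcome: SurvivalOutcome):
    return Surv.from_arrays(event=outcome.event.astype(bool), time=outcome.time)


def clinical_cox(outcome: SurvivalOutcome, X: ClinicalTable) -> ClinicalCoxResults:
    """Cox proportional hazards fit on fixed covariates (Breslow ties).

    Standard errors come from the inverse observed information of the
    partial likelihood at the estimate.
    """
    if outcome.n_events == 0:
        raise ValueError("no events in outcome")
    mat = X.values.to_numpy(float)
    _check_full_rank(mat - mat.mean(axis=0), X.covariate_names)
    est = CoxPHSurvivalAnalysis(ties="breslow")
    est.fit(mat, _surv_y(outcome))
    beta = np.asarray(est.coef_, float)
    _, _, H = cox_partial_loglik(mat @ beta, outcome)
    info = -(mat.T @ H @ mat)
    cov = np.linalg.inv(info)
    return ClinicalCoxResults(
        beta=pd.Series(beta, index=X.covariate_names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=X.covariate_names),
    )


def _heldout_loglik(coefs: np.ndarray, Z: np.ndarray, outcome: SurvivalOutcome) -> np.ndarray:
    out = np.empty(coefs.shape[1])
    for a in range(coefs.shape[1]):
        eta = Z @ coefs[:, a]
        out[a] = cox_partial_loglik(eta, outcome)[0]
    return out


def lasso_cox_signature(
    outcome: SurvivalOutcome,
    Z: OmicMatrix,
    n_alphas: int = 50,
    inner_folds: int = 5,
    seed: int = 0,
    alpha_min_ratio: float = 0.01,
) -> tuple[LassoSignature, pd.Series]:
    """L1-penalized Cox biomarker selection with inner-CV penalty choice.

    The penalty path is computed by Coxnet; the penalty maximizing the
    summed held-out Cox partial log-likelihood over ``inner_folds``
    cross-validation folds is selected, then the model is refit on all
    training subjects.  Deterministic given the seed.  Returns the
    signature and the training risk scores.
    """
    from sklearn.model_selection import KFold

    arr = Z.values.to_numpy(float)
    y = _surv_y(outcome)
    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio
    )
    path.fit(arr, y)
    alphas = np.asarray(path.alphas_)

    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    score = np.zeros(len(alphas))
    used = np.zeros(len(alphas))
    for tr, ho in kf.split(arr):
        ho_out = SurvivalOutcome(outcome.values.iloc[ho])
        if ho_out.n_events == 0:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        tr_out = SurvivalOutcome(outcome.values.iloc[tr])
        m.fit(arr[tr], _surv_y(tr_out))
        fitted = np.asarray(m.alphas_)
        idx = [np.argmin(np.abs(alphas - a)) for a in fitted]
        score[idx] += _heldout_loglik(np.asarray(m.coef_), arr[ho], ho_out)
        used[idx] += 1
    valid = used > 0
    if not valid.any():
        raise ValueError("no usable inner-CV folds (too few events)")
    mean_score = np.where(valid, score / np.maximum(used, 1), -np.inf)
    best = float(alphas[int(np.argmax(mean_score))])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[best])
    final.fit(arr, y)
    coef = pd.Series(np.asarray(final.coef_).ravel(), index=Z.biomarker_ids)
    selected = coef.index[coef != 0].tolist()
    sig = LassoSignature(
        selected=selected,
        coefficients=coef[coef != 0],
        penalty=best,
        seed=seed,
        empty=len(selected) == 0,
    )
    risk = pd.Series(arr @ coef.to_numpy(), index=Z.subject_ids)
    return sig, risk


def genelist_score(Z: OmicMatrix, gene_list: Sequence[str], name: str = "signature") -> SignatureScore:
    """Per-subject unweighted mean expression over the listed genes.

    Genes absent from the profile are skipped (and reported via the
    returned score's name attribute holders); at least one listed gene
    must be present.
    """
    present = [g for g in gene_list if g in Z.values.columns]
    if not present:
        raise ValueError(f"no gene of signature {name!r} present in profile")
    scores = Z.values.loc[:, present].mean(axis=1)
    return SignatureScore(name=name, scores=scores)


def prs_score(
    dosages: OmicMatrix,
    weights: pd.Series,
    max_missing_frac: float = 0.1,
    name: str = "PRS",
) -> SignatureScore:
    """Polygenic risk score: weighted allele-dosage sum per subject.

    ``weights`` maps SNP ids to log odds ratios (effect-allele scale);
    dosages are 0/1/2 counts.  SNPs missing from the dosage matrix beyond
    ``max_missing_frac`` raise; missing dosage cells are mean-imputed
    per SNP.
    """
    snps = [s for s in weights.index if s in dosages.values.columns]
    frac_missing = 1.0 - len(snps) / len(weights)
    if frac_missing > max_missing_frac:
        raise ValueError(
            f"{frac_missing:.0%} of weighted SNPs absent from dosages "
            f"(limit {max_missing_frac:.0%})"
        )
    D = dosages.values.loc[:, snps]
    if D.isna().any().any():
        D = D.fillna(D.mean(axis=0))
    scores = pd.Series(
        D.to_numpy(float) @ weights.loc[snps].to_numpy(float), index=dosages.subject_ids
    )
    return SignatureScore(name=name, scores=scores)


def covariate_signature_cox(
    outcome: SurvivalOutcome,
    scores: Sequence[SignatureScore] = (),
    labels: Optional[pd.Series] = None,
) -> tuple[ClinicalCoxResults, np.ndarray]:
    """Cox model on externally supplied signature scores and/or subtype labels.

    Labels (e.g. PAM50 subtypes) expand to drop-first indicator columns.
    Returns the fit and the training risk scores.
    """
    cols = {}
    for s in scores:
        cols[s.name] = s.scores
    df = pd.DataFrame(cols)
    if labels is not None:
        dummies = pd.get_dummies(labels, prefix=labels.name or "subtype", drop_first=True, dtype=float)
        df = pd.concat([df, dummies], axis=1) if len(df.columns) else dummies
    if df.empty:
        raise ValueError("no signature scores or labels supplied")
    df = df.loc[outcome.subject_ids]
    table = ClinicalTable(df)
    fit = clinical_cox(outcome, table)
    return fit, fit.risk(table)


# ---------------------------------------------------------------------------
# uniform fit/score comparators for the cross-validation harness
# ---------------------------------------------------------------------------

def _preprocess_train(profiles: Sequence[OmicMatrix], max_missing_frac: float = 0.2):
    """Training-only preprocessing: filter/impute and standardize continuous
    profiles; binary profiles pass through untouched."""
    processed, stats = [], {}
    for Z in profiles:
        if Z.profile_kind == BINARY:
            processed.append(Z)
            stats[Z.profile_name] = None
        else:
            Zf, _ = impute_and_filter(Z, max_missing_frac=max_missing_frac)
            Zs, st = standardize_profile(Zf)
            processed.append(Zs)
            stats[Z.profile_name] = st
    return processed, stats


def _apply_stats(profiles: Sequence[OmicMatrix], stats: dict, train: Sequence[OmicMatrix]):
    """Validation preprocessing with frozen training statistics."""
    out = []
    for Z, Zt in zip(profiles, train):
        st = stats[Z.profile_name]
        if st is None:  # binary: restrict to training biomarkers
            out.append(Z.subset_biomarkers(Zt.biomarker_ids))
        else:
            Zs, _ = standardize_profile(Z, st)
            if Zs.values.isna().any().any():
                Zs = OmicMatrix(
                    Zs.values.fillna(0.0), Zs.profile_kind, Zs.profile_name
                )  # training mean on the standardized scale
            out.append(Zs)
    return out


class ClinicalCoxMethod:
    """Clinical-covariates-only Cox comparator."""

    name = "clinical"

    def fit(self, outcome, clinical, profiles):
        if clinical is None:
            raise ValueError("clinical method needs a clinical table")
        self._fit = clinical_cox(outcome, clinical)
        return self

    def score(self, clinical, profiles):
        return self._fit.risk(clinical)


class KernelMethod:
    """Kernel-fusion Cox comparator (one or more profiles, +/- clinical)."""

    def __init__(self, profile_names: Optional[Sequence[str]] = None, with_clinical: bool = False):
        self.profile_names = profile_names
        self.with_clinical = with_clinical
        sel = "+".join(profile_names) if profile_names else "all"
        self.name = f"kernel_{sel}" + ("+clinical" if with_clinical else "")

    def _select(self, profiles):
        if self.profile_names is None:
            return list(profiles)
        by_name = {Z.profile_name: Z for Z in profiles}
        return [by_name[n] for n in self.profile_names]

    def fit(self, outcome, clinical, profiles):
        sel = self._select(profiles)
        self._train, self._stats = _preprocess_train(sel)
        model = KernelCoxPH(
            outcome,
            profiles=self._train,
            clinical=clinical if self.with_clinical else None,
            stats=self._stats,
        )
        self.results = model.fit()
        return self

    def score(self, clinical, profiles):
        sel = self._select(profiles)
        proc = _apply_stats(sel, self._stats, self._train)
        pred = self.results.predict(
            clinical=clinical if self.with_clinical else None, profiles=proc
        )
        return pred.eta_v


class LassoMethod:
    """L1-penalized Cox signature comparator on one continuous profile."""

    def __init__(self, profile_name: Optional[str] = None, seed: int = 0, **kwargs):
        self.profile_name = profile_name
        self.seed = seed
        self.kwargs = kwargs
        self.name = f"lasso_{profile_name or 'first'}"

    def _select(self, profiles):
        if self.profile_name is None:
            return profiles[0]
        return next(Z for Z in profiles if Z.profile_name == self.profile_name)

    def fit(self, outcome, clinical, profiles):
        Z = self._select(profiles)
        (self._train,), self._stats = _preprocess_train([Z])
        self.signature, _ = lasso_cox_signature(
            outcome, self._train, seed=self.seed, **self.kwargs
        )
        return self

    def score(self, clinical, profiles):
        Z = self._select(profiles)
        (Zs,) = _apply_stats([Z], self._stats, [self._train])
        if self.signature.empty:
            return np.zeros(Zs.n_subjects)
        coef = self.signature.coefficients
        return Zs.values.loc[:, coef.index].to_numpy(float) @ coef.to_numpy()


class GeneListSignatureMethod:
    """Cox model on fixed gene-list average-expression scores."""

    def __init__(self, gene_lists: dict, profile_name: Optional[str] = None):
        self.gene_lists = gene_lists
        self.profile_name = profile_name
        self.name = "signature_" + "+".join(gene_lists)

    def _select(self, profiles):
        if self.profile_name is None:
            return profiles[0]
        return next(Z for Z in profiles if Z.profile_name == self.profile_name)

    def _scores(self, Z):
        return [genelist_score(Z, genes, name) for name, genes in self.gene_lists.items()]

    def fit(self, outcome, clinical, profiles):
        Z = self._select(profiles)
        (self._train,), self._stats = _preprocess_train([Z])
        self._fit, _ = covariate_signature_cox(outcome, self._scores(self._train))
        return self

    def score(self, clinical, profiles):
        Z = self._select(profiles)
        (Zs,) = _apply_stats([Z], self._stats, [self._train])
        df = pd.DataFrame({s.name: s.scores for s in self._scores(Zs)})
        return self._fit.risk(df)
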