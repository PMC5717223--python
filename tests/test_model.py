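import numpy as np
import pandas as pd
import pytest

from kernsurv import (
    KernelCoxPH,
    build_linear_kernel,
    blup_predict,
    cox_partial_loglik,
    fit_ppl,
)
from kernsurv.baselines import clinical_cox, _preprocess_train

from conftest import make_omic, make_outcome, standardized_random_omic


def naive_breslow_loglik(eta, time, event):
    """Independent loop-based Breslow partial log-likelihood oracle."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        D = np.where((time == t) & (event == 1))[0]
        R = np.where(time >= t)[0]
        ll += float(np.sum(eta[D])) - len(D) * np.log(np.sum(np.exp(eta[R])))
    return ll


def _random_case(n, seed, with_ties=False):
    rng = np.random.default_rng(seed)
    time = rng.exponential(1.0, n)
    if with_ties:
        time = np.ceil(time * 4) / 4  # coarse grid forces tied times
    event = (rng.random(n) < 0.7).astype(int)
    if event.sum() == 0:
        event[0] = 1
    eta = rng.normal(0, 1, n)
    return eta, make_outcome(time, event)


def test_partial_loglik_hand_value():
    # two subjects, times (1, 2), both events, eta = 0:
    # log(1/2) for the first risk set plus log(1) for the second
    out = make_outcome([1.0, 2.0], [1, 1])
    ll, _, _ = cox_partial_loglik(np.zeros(2), out)
    assert ll == pytest.approx(np.log(0.5), abs=1e-12)


@pytest.mark.parametrize("with_ties", [False, True])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_partial_loglik_matches_naive_oracle(seed, with_ties):
    eta, out = _random_case(25, seed, with_ties)
    ll, _, _ = cox_partial_loglik(eta, out)
    assert ll == pytest.approx(naive_breslow_loglik(eta, out.time, out.event), abs=1e-10)


def test_partial_loglik_gradient_and_hessian_by_finite_differences():
    eta, out = _random_case(12, 42, with_ties=True)
    ll, grad, hess = cox_partial_loglik(eta, out)
    h = 1e-6
    for k in range(12):
        e = np.zeros(12)
        e[k] = h
        lp = cox_partial_loglik(eta + e, out)[0]
        lm = cox_partial_loglik(eta - e, out)[0]
        assert grad[k] == pytest.approx((lp - lm) / (2 * h), abs=1e-6)
        gp = cox_partial_loglik(eta + e, out)[1]
        gm = cox_partial_loglik(eta - e, out)[1]
        np.testing.assert_allclose(hess[:, k], (gp - gm) / (2 * h), atol=1e-5)


def test_partial_loglik_hessian_negative_semidefinite():
    eta, out = _random_case(20, 9)
    _, _, hess = cox_partial_loglik(eta, out)
    w = np.linalg.eigvalsh((hess + hess.T) / 2)
    assert w.max() < 1e-10


def test_partial_loglik_rejects_bad_input():
    out = make_outcome([1.0, 2.0], [1, 0])
    with pytest.raises(ValueError, match="non-finite"):
        cox_partial_loglik(np.array([np.inf, 0.0]), out)
    none = make_outcome([1.0, 2.0], [0, 0])
    with pytest.raises(ValueError, match="no events"):
        cox_partial_loglik(np.zeros(2), none)


def test_fit_ppl_zero_kernel_reduces_to_plain_cox(small_cohort):
    """With no omic variance the fixed effects must match an independent
    plain Cox fit (scikit-survival under clinical_cox)."""
    X = small_cohort.clinical.values.to_numpy(float)
    n = len(small_cohort.outcome.subject_ids)
    fit = fit_ppl(small_cohort.outcome, X, np.zeros((n, n)))
    ref = clinical_cox(small_cohort.outcome, small_cohort.clinical)
    np.testing.assert_allclose(fit.beta, ref.beta.to_numpy(), atol=1e-6)
    assert np.max(np.abs(fit.g)) < 1e-6


def test_fit_ppl_increases_objective_monotonically(small_cohort):
    K = build_linear_kernel(small_cohort.profiles[0]).to_numpy()
    fit = fit_ppl(small_cohort.outcome, None, K)
    diffs = np.diff(fit.objective_trace)
    assert np.all(diffs >= -1e-9)
    # rank-deficient kernel (p < n): the jittered inverse has condition
    # number ~1e8, so only the solver's fallback gradient level is reachable
    assert fit.gradient_norm < 1e-4


def test_fit_ppl_rejects_collinear_design(small_cohort):
    X = small_cohort.clinical.values.to_numpy(float)
    X2 = np.column_stack([X, X[:, 0] * 2.0])
    n = X.shape[0]
    with pytest.raises(ValueError, match="rank deficient"):
        fit_ppl(small_cohort.outcome, X2, np.eye(n), covariate_names=["a", "b", "c"])


def test_blup_zero_cross_kernel_gives_zero():
    g = np.array([0.5, -0.2, 0.1])
    K_TT = np.eye(3)
    pred = blup_predict(g, np.zeros((2, 3)), K_TT)
    np.testing.assert_allclose(pred, 0.0, atol=1e-15)


def test_blup_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension mismatch"):
        blup_predict(np.zeros(3), np.zeros((2, 4)), np.eye(3))


def test_blup_duplicated_subject_reproduces_training_blup(small_cohort):
    """Predicting a subject identical to training subject i returns g_i."""
    Z = small_cohort.profiles[0]
    K = build_linear_kernel(Z)
    model = KernelCoxPH(small_cohort.outcome, kernels=[K])
    res = model.fit(sigma2=[1.0])
    K_TT = model._fused(res.sigma2_hat.to_numpy())
    K_VT = K_TT[[4, 17], :]  # rows of two duplicated training subjects
    pred = res.predict_g(K_VT, K_TT)
    np.testing.assert_allclose(pred, res.g_hat.to_numpy()[[4, 17]], atol=1e-6)


def test_model_constructor_validation(small_cohort):
    K = build_linear_kernel(small_cohort.profiles[0])
    with pytest.raises(ValueError, match="exactly one of"):
        KernelCoxPH(small_cohort.outcome, profiles=small_cohort.profiles, kernels=[K])
    with pytest.raises(ValueError, match="exactly one of"):
        KernelCoxPH(small_cohort.outcome)
    # subject order mismatch between outcome and kernel
    ids = small_cohort.outcome.subject_ids
    shuffled = small_cohort.outcome.subset_subjects(ids[::-1])
    with pytest.raises(ValueError, match="differ from the outcome"):
        KernelCoxPH(shuffled, kernels=[K])


def test_fixed_sigma2_fit_and_summary(small_cohort):
    model = KernelCoxPH(
        small_cohort.outcome,
        profiles=small_cohort.profiles,
        clinical=small_cohort.clinical,
    )
    res = model.fit(sigma2=[0.8])
    assert res.sigma2_hat.to_list() == [0.8]
    assert res.n_outer_evals == 0
    assert set(res.beta_hat.index) == {"cov0", "cov1"}
    assert (res.bse() > 0).all()
    text = res.summary()
    assert "Variance components" in text and "Fixed effects" in text
    assert len(res.eta_train) == 60
    d = res.to_dict()
    assert set(d) == {"beta", "sigma2", "g_train", "criterion", "no_signal"}


def test_estimated_fit_recovers_signal_direction():
    """On densely signal-bearing data the fitted eta must track the true
    prognostic score and beta must carry the right signs."""
    from kernsurv import ProfileSpec, generate_cohort

    ds = generate_cohort(
        n=120,
        profiles=[ProfileSpec("mRNA", 60, "continuous", 2.0)],
        n_covariates=2,
        beta=[0.5, -0.3],
        censoring_rate=0.3,
        seed=3,
    )
    model = KernelCoxPH(ds.outcome, profiles=ds.profiles, clinical=ds.clinical)
    res = model.fit()
    assert not res.no_signal
    corr = np.corrcoef(res.eta_train.to_numpy(), ds.eta)[0, 1]
    assert corr > 0.5
    assert res.beta_hat["cov0"] > 0 and res.beta_hat["cov1"] < 0


def test_laplace_criterion_at_optimum_not_lower_than_nearby(small_cohort):
    model = KernelCoxPH(small_cohort.outcome, profiles=small_cohort.profiles)
    res = model.fit()
    s2 = res.sigma2_hat.to_numpy()
    c_opt = model.laplace_criterion(s2)[0]
    for factor in (0.5, 2.0):
        c_near = model.laplace_criterion(np.clip(s2 * factor, 1e-6, 1e3))[0]
        assert c_opt >= c_near - 1e-3


def test_two_kernel_fit_runs(two_profile_cohort):
    processed, stats = _preprocess_train(two_profile_cohort.profiles)
    model = KernelCoxPH(
        two_profile_cohort.outcome,
        profiles=processed,
        clinical=two_profile_cohort.clinical,
        stats=stats,
    )
    res = model.fit()
    assert list(res.sigma2_hat.index) == ["mRNA", "mutation"]
    assert (res.sigma2_hat >= 0).all()


def test_predict_requires_matching_biomarkers(small_cohort):
    model = KernelCoxPH(small_cohort.outcome, profiles=small_cohort.profiles)
    res = model.fit(sigma2=[1.0])
    bad = small_cohort.profiles[0].subset_biomarkers(
        small_cohort.profiles[0].biomarker_ids[:10]
    )
    with pytest.raises(ValueError, match="biomarkers differ"):
        res.predict(profiles=[bad])


def test_predict_on_training_profiles_matches_g(small_cohort):
    model = KernelCoxPH(small_cohort.outcome, profiles=small_cohort.profiles)
    res = model.fit(sigma2=[1.0])
    pred = res.predict(profiles=small_cohort.profiles)
    np.testing.assert_allclose(pred.g_v, res.g_hat.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(pred.eta_v, pred.b_v + pred.g_v)
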