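import numpy as np
import pandas as pd
import pytest

from kernsurv import (
    ProfileSpec,
    concordance_index,
    cv_results_to_table,
    downsample_experiment,
    external_validate,
    generate_cohort,
    make_method,
    monte_carlo_cv,
)
from kernsurv.baselines import KernelMethod, _preprocess_train
from kernsurv.evaluation import _Subset
from kernsurv.model import KernelCoxPH

from conftest import make_outcome


def brute_force_cindex(time, event, risk):
    """Independent pair-enumeration oracle for Harrell's C (no tied times)."""
    conc = comp = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / comp


def test_cindex_perfect_and_reversed():
    out = make_outcome([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    assert concordance_index(out, np.array([4.0, 3.0, 2.0, 1.0])) == 1.0
    assert concordance_index(out, np.array([1.0, 2.0, 3.0, 4.0])) == 0.0


def test_cindex_risk_ties_count_half():
    out = make_outcome([1.0, 2.0], [1, 1])
    assert concordance_index(out, np.array([0.7, 0.7])) == 0.5


def test_cindex_no_comparable_pairs_errors():
    out = make_outcome([1.0, 2.0], [0, 0])
    with pytest.raises(ValueError, match="no comparable pairs"):
        concordance_index(out, np.array([1.0, 2.0]))


def test_cindex_length_mismatch():
    out = make_outcome([1.0, 2.0], [1, 0])
    with pytest.raises(ValueError, match="lengths differ"):
        concordance_index(out, np.array([1.0]))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cindex_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = 80
    time = rng.exponential(1.0, n)  # continuous: no tied times
    event = (rng.random(n) < 0.6).astype(int)
    risk = np.round(rng.normal(0, 1, n), 1)  # rounded: tied risks occur
    out = make_outcome(time, event)
    assert concordance_index(out, risk) == pytest.approx(
        brute_force_cindex(time, event, risk), abs=1e-12
    )


def test_cindex_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    time = rng.exponential(1.0, 40)
    event = (rng.random(40) < 0.7).astype(int)
    risk = rng.normal(0, 1, 40)
    out = make_outcome(time, event)
    assert concordance_index(out, risk) == pytest.approx(
        concordance_index(out, np.exp(2.0 * risk)), abs=1e-12
    )


def test_make_method_specs():
    assert make_method("clinical").name == "clinical"
    assert make_method("kernel:mRNA").name == "kernel_mRNA"
    assert make_method("kernel:mRNA+miRNA").profile_names == ["mRNA", "miRNA"]
    assert make_method("kernel+clinical:mRNA").with_clinical
    assert make_method("lasso:mRNA").name == "lasso_mRNA"
    with pytest.raises(ValueError, match="unknown method spec"):
        make_method("boosting")


@pytest.fixture(scope="module")
def signal_cohort():
    return generate_cohort(
        n=80,
        profiles=[ProfileSpec("mRNA", 50, "continuous", 2.0)],
        n_covariates=2,
        beta=[0.5, 0.0],
        censoring_rate=0.3,
        seed=21,
    )


def test_monte_carlo_cv_deterministic_and_beats_chance(signal_cohort):
    res1 = monte_carlo_cv(signal_cohort, "kernel:mRNA", repeats=5, base_seed=3)
    res2 = monte_carlo_cv(signal_cohort, "kernel:mRNA", repeats=5, base_seed=3)
    assert res1.cindices == res2.cindices
    res3 = monte_carlo_cv(signal_cohort, "kernel:mRNA", repeats=5, base_seed=4)
    assert res1.cindices != res3.cindices
    assert res1.mean > 0.5  # dense signal must rank better than chance
    frame = res1.to_frame()
    assert list(frame.columns) == ["method", "repeat", "cindex"]


def test_monte_carlo_cv_uses_frozen_training_stats(signal_cohort):
    """A constant shift of the validation profile must shift through the
    frozen training standardization, not be re-standardized away: scoring
    the shifted cohort with a model fit on the original training half
    changes predictions."""
    method = KernelMethod(profile_names=["mRNA"])
    ids = signal_cohort.outcome.subject_ids
    tr_ids, va_ids = ids[:60], ids[60:]
    tr = _Subset(
        signal_cohort.outcome.subset_subjects(tr_ids),
        None,
        [Z.subset_subjects(tr_ids) for Z in signal_cohort.profiles],
    )
    method.fit(tr.outcome, None, tr.profiles)
    va_prof = signal_cohort.profiles[0].subset_subjects(va_ids)
    base = method.score(None, [va_prof])
    shifted = type(va_prof)(va_prof.values + 5.0, va_prof.profile_kind, va_prof.profile_name)
    moved = method.score(None, [shifted])
    assert np.max(np.abs(np.asarray(base) - np.asarray(moved))) > 1e-8


def test_monte_carlo_cv_requires_enough_subjects():
    tiny = generate_cohort(n=20, seed=0)
    with pytest.raises(ValueError, match="at least 25"):
        monte_carlo_cv(tiny, "clinical", repeats=2)


def test_monte_carlo_cv_skips_eventless_validation_splits():
    # 30 subjects, three events: event-free 6-subject validation splits are
    # common enough to trip the 20% skip guard
    cohort = generate_cohort(n=30, seed=0, censoring_rate=0.0)
    vals = cohort.outcome.values.copy()
    vals["event"] = 0
    vals.iloc[[0, 1, 2], vals.columns.get_loc("event")] = 1
    sparse = _Subset(type(cohort.outcome)(vals), cohort.clinical, cohort.profiles)
    with pytest.raises(ValueError, match="event-free validation"):
        monte_carlo_cv(sparse, "clinical", repeats=10, base_seed=0)


def test_external_validate_roundtrip(signal_cohort):
    processed, stats = _preprocess_train(signal_cohort.profiles)
    model = KernelCoxPH(
        signal_cohort.outcome,
        profiles=processed,
        clinical=signal_cohort.clinical,
        stats=stats,
    )
    results = model.fit(sigma2=[1.0])
    external = generate_cohort(
        n=40,
        profiles=[ProfileSpec("mRNA", 50, "continuous", 2.0)],
        n_covariates=2,
        censoring_rate=0.3,
        seed=99,
    )
    c, report = external_validate(results, external)
    assert 0.0 <= c <= 1.0
    assert report["mRNA"]["overlap"] == 1.0


def test_external_validate_overlap_floor(signal_cohort):
    processed, stats = _preprocess_train(signal_cohort.profiles)
    model = KernelCoxPH(signal_cohort.outcome, profiles=processed, stats=stats)
    results = model.fit(sigma2=[1.0])
    external = generate_cohort(
        n=40, profiles=[ProfileSpec("mRNA", 50, "continuous", 1.0)], seed=98
    )
    # keep only 20% of biomarkers in the external profile
    few = external.profiles[0].subset_biomarkers(external.profiles[0].biomarker_ids[:10])
    crippled = _Subset(external.outcome, external.clinical, [few])
    with pytest.raises(ValueError, match="below the 50% floor"):
        external_validate(results, crippled)


def test_downsample_validation_errors(signal_cohort):
    with pytest.raises(ValueError, match="strictly decreasing"):
        downsample_experiment(signal_cohort, "subjects", [40, 60], repetitions=1)
    with pytest.raises(ValueError, match="axis"):
        downsample_experiment(signal_cohort, "genes", [60, 40], repetitions=1)
    with pytest.raises(ValueError, match="exceeds available"):
        downsample_experiment(signal_cohort, "subjects", [500, 60], repetitions=1)


def test_downsample_runs_both_axes(signal_cohort):
    g1 = downsample_experiment(
        signal_cohort, "subjects", [60, 40], repetitions=1, inner_cv_folds=3
    )
    assert g1.sizes == [60, 40] and len(g1.means) == 2
    g2 = downsample_experiment(
        signal_cohort, "biomarkers", [50, 20], repetitions=1, inner_cv_folds=3
    )
    assert all(0.0 <= m <= 1.0 for m in g2.means)
    assert list(g1.to_frame().columns) == ["size", "mean_cindex"]


def test_cv_results_to_table(signal_cohort):
    res = monte_carlo_cv(signal_cohort, "clinical", repeats=3, base_seed=0)
    table = cv_results_to_table([res], cohort="SYN")
    assert table.records.iloc[0]["cohort"] == "SYN"
    assert table.records.iloc[0]["method"] == "clinical"
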