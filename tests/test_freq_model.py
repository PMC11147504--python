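import numpy as np
import pytest

import shotadapt as sa
from shotadapt.hier_bayes import ModelData


def _flat(y, e, s, n_epochs=2, n_subjects=2):
    return ModelData(
        errors=np.asarray(y, float),
        epoch_idx=np.asarray(e, int),
        subject_idx=np.asarray(s, int),
        n_epochs=n_epochs,
        n_subjects=n_subjects,
    )


def test_zero_fish_effect_gives_near_zero_intercept_variance():
    ss = sa.simulate_experiment(
        "exp1", n_fish=4, sessions_per_fish=3, fish_effect_sd=0.0, seed=21
    )
    mf = sa.fit_mixed(sa.build_model_data(ss))
    assert mf.random_intercept_var < 0.5


def test_fixed_effects_recover_epoch_means():
    ss = sa.simulate_experiment("exp1", seed=17)
    data = sa.build_model_data(ss)
    mf = sa.fit_mixed(data)
    # onset contrast: fitted epoch-2 minus epoch-1 mean vs generating value
    est = mf.fixed_epoch_means[2] - mf.fixed_epoch_means[1]
    se = float(mf.result.bse["C(epoch)[T.2]"])
    true = 5.0 * (1 + 0.8) / 2
    assert abs(est - true) < 3 * se


def test_one_fish_removed_refit_is_stable():
    ss = sa.simulate_experiment("exp1", n_fish=4, sessions_per_fish=3, seed=23)
    full = sa.fit_mixed(sa.build_model_data(ss))
    kept = sa.SessionSet(
        tuple(s for s in ss if s.fish_id != "fish4")
    )
    reduced = sa.fit_mixed(sa.build_model_data(kept))
    est_full = full.fixed_epoch_means[2] - full.fixed_epoch_means[1]
    est_red = reduced.fixed_epoch_means[2] - reduced.fixed_epoch_means[1]
    assert abs(est_full - est_red) < 2.0


def test_too_few_epochs_or_fish_rejected():
    y = np.zeros(10)
    with pytest.raises(ValueError, match="epochs"):
        sa.fit_mixed(_flat(y, np.zeros(10), np.repeat([0, 1], 5)))
    with pytest.raises(ValueError, match="fish"):
        sa.fit_mixed(_flat(y, np.repeat([0, 1], 5), np.zeros(10), n_subjects=1))


def test_eta2_limits():
    rng = np.random.default_rng(3)
    n = 40
    e = np.tile([0, 1, 2], n)[: 3 * n]
    s = np.tile([0, 1], (3 * n) // 2 + 1)[: 3 * n]
    # epoch means 0/5/10 with negligible noise: eta2 -> 1
    y = np.array([0.0, 5.0, 10.0])[e] + rng.normal(0, 1e-3, 3 * n)
    mf = sa.fit_mixed(_flat(y, e, s, n_epochs=3))
    assert sa.anova_eta2(mf).eta2 > 0.999
    # no epoch effect: eta2 near 0
    y0 = rng.normal(0, 1.0, 3 * n)
    mf0 = sa.fit_mixed(_flat(y0, e, s, n_epochs=3))
    assert sa.anova_eta2(mf0).eta2 < 0.1


def test_partial_eta2_at_least_classical():
    ss = sa.simulate_experiment("exp1", n_fish=3, sessions_per_fish=2, seed=29)
    mf = sa.fit_mixed(sa.build_model_data(ss))
    classical = sa.anova_eta2(mf).eta2
    partial = sa.anova_eta2(mf, partial=True).eta2
    assert partial >= classical


def test_posthoc_identical_epochs():
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.concatenate([vals, vals])
    e = np.repeat([0, 1], 4)
    s = np.tile([0, 1], 4)
    mf = sa.fit_mixed(_flat(y, e, s))
    row = sa.posthoc(mf, [(1, 2)]).iloc[0]
    assert row["t"] == pytest.approx(0.0, abs=1e-10)
    assert row["p_adj"] == pytest.approx(1.0)
    assert row["cohens_d"] == pytest.approx(0.0, abs=1e-10)


def test_bonferroni_family_of_one_is_identity():
    ss = sa.simulate_experiment("exp1", n_fish=3, sessions_per_fish=2, seed=31)
    mf = sa.fit_mixed(sa.build_model_data(ss))
    one = sa.posthoc(mf, [(2, 4)]).iloc[0]
    assert one["p_adj"] == pytest.approx(min(1.0, one["p_raw"]))


def test_bonferroni_never_below_raw():
    ss = sa.simulate_experiment("exp1", n_fish=3, sessions_per_fish=2, seed=37)
    mf = sa.fit_mixed(sa.build_model_data(ss))
    tab = sa.posthoc(mf, sa.DESIGN_CONTRAST_PAIRS["exp1"])
    assert (tab["p_adj"] >= tab["p_raw"] - 1e-15).all()


def test_posthoc_empty_epoch_flagged_not_dropped():
    ss = sa.simulate_experiment("exp1", n_fish=3, sessions_per_fish=2, seed=41)
    mf = sa.fit_mixed(sa.build_model_data(ss))
    tab = sa.posthoc(mf, [(1, 2), (6, 5)])
    assert len(tab) == 2
    # epoch 6 exists here, so fabricate an empty pair via an absent epoch
    data = sa.build_model_data(ss)
    sub = ModelData(
        errors=data.errors[data.epoch_idx != 5],
        epoch_idx=data.epoch_idx[data.epoch_idx != 5],
        subject_idx=data.subject_idx[data.epoch_idx != 5],
        n_epochs=6,
        n_subjects=data.n_subjects,
        subject_ids=data.subject_ids,
    )
    mf2 = sa.fit_mixed(sub)
    tab2 = sa.posthoc(mf2, [(1, 6)])
    assert tab2.iloc[0]["flag"] == "empty_epoch"


def test_posthoc_d_calibration_over_replicates():
    """Across 200 simulated cohorts the mean post hoc Cohen's d for the
    onset pair sits within 0.1 of the generating standardized effect."""
    true_d = (5.0 * (1 + 0.8) / 2) / 3.2
    ds = []
    for seed in range(200):
        ss = sa.simulate_experiment(
            "exp1", n_fish=7, sessions_per_fish=1, seed=7000 + seed
        )
        mf = sa.fit_mixed(sa.build_model_data(ss))
        ds.append(float(sa.posthoc(mf, [(2, 1)]).iloc[0]["cohens_d"]))
    assert np.mean(ds) == pytest.approx(true_d, abs=0.1)


def test_cross_engine_epoch_estimates_agree(exp1_fit):
    """Bayesian pooled cell-mean contrast and mixed-model fixed-effect
    contrast agree within 2 SE on the same data."""
    data, post = exp1_fit
    c = sa.epoch_contrast(post, 2, 1)
    mf = sa.fit_mixed(data)
    freq = mf.fixed_epoch_means[2] - mf.fixed_epoch_means[1]
    se = float(mf.result.bse["C(epoch)[T.2]"])
    assert abs(c.diff_mean - freq) < 2 * se


def test_estimator_wrapper():
    ss = sa.simulate_experiment("exp1", n_fish=3, sessions_per_fish=2, seed=43)
    est = sa.MixedEffectsShotModel().fit(sa.build_model_data(ss))
    assert 0.0 <= est.anova_.eta2 <= 1.0
    assert est.random_intercept_var_ >= 0.0
    means = est.predict()
    assert set(means) == set(range(1, 7))
    tab = est.posthoc(sa.DESIGN_CONTRAST_PAIRS["exp1"])
    assert len(tab) == 3
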