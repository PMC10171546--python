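from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from connectodev.models import (
    ModelConfig,
    ModelFit,
    age_spline_basis,
    fdr_correct,
    fit_nested_models,
    fit_random_intercept_ml,
    predict_trajectories,
    regionwise_analysis,
    select_best_model,
)


def _cohort_frame(rng, n_subj=60, group_offset=0.0, age_slope_adhd=0.0, noise=1.0,
                  subject_sd=0.5, region="r0", metric="degree"):
    rows = []
    for s in range(n_subj):
        u = rng.normal(0, subject_sd)
        grp = "ADHD" if s < n_subj // 2 else "control"
        for w in range(1, 4):
            age = [10.4, 11.6, 13.2][w - 1] + rng.normal(0, 0.5)
            val = u + rng.normal(0, noise)
            if grp == "ADHD":
                val += group_offset + age_slope_adhd * (age - 9.0)
            rows.append(
                dict(subject_id=f"s{s:03d}", wave=w, age=age, group=grp,
                     sex="M" if s % 2 else "F", fd=abs(rng.normal(0.15, 0.05)),
                     scanner="post_upgrade" if w == 3 else "pre_upgrade",
                     medicated=grp == "ADHD" and s % 5 == 0, value=val,
                     region_label=region, metric_name=metric, scan_id=f"s{s:03d}w{w}")
            )
    return pd.DataFrame(rows)


class TestSplineBasis:
    def test_dimension_and_clamping(self):
        age = np.linspace(9, 14, 50)
        b = age_spline_basis(age, basis_dim=4)
        assert b.shape == (50, 3)
        outside = age_spline_basis(np.array([5.0, 20.0]), 4, bounds=(9.0, 14.0))
        inside = age_spline_basis(np.array([9.0, 14.0]), 4, bounds=(9.0, 14.0))
        np.testing.assert_allclose(outside, inside)


class TestRandomInterceptML:
    def test_matches_statsmodels_mixedlm(self):
        """The profiled-likelihood fit is exact ML: cross-check against the
        general-purpose mixed-model optimizer on the same data."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(7)
        n_subj, waves = 50, 3
        subj = np.repeat(np.arange(n_subj), waves)
        x = np.column_stack([np.ones(n_subj * waves), rng.normal(size=(n_subj * waves, 4))])
        beta = rng.normal(size=5)
        y = x @ beta + rng.normal(0, 0.8, n_subj)[subj] + rng.normal(size=n_subj * waves)
        mine = fit_random_intercept_ml(y, x, subj, [f"c{i}" for i in range(5)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MixedLM(y, x, subj).fit(reml=False)
        assert mine["loglik"] == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(mine["params"], ref.fe_params, atol=1e-5)
        assert mine["var_resid"] == pytest.approx(ref.scale, rel=1e-4)
        assert mine["var_subject"] == pytest.approx(np.asarray(ref.cov_re)[0, 0], rel=1e-3, abs=1e-6)

    def test_boundary_no_subject_variance(self):
        rng = np.random.default_rng(8)
        subj = np.repeat(np.arange(40), 3)
        x = np.column_stack([np.ones(120), rng.normal(size=(120, 2))])
        y = x @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=120)
        r = fit_random_intercept_ml(y, x, subj, ["a", "b", "c"])
        assert r["var_subject"] < 0.05

    def test_rank_deficient_design_names_column(self):
        x = np.column_stack([np.ones(30), np.arange(30.0), 2 * np.arange(30.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_random_intercept_ml(np.zeros(30), x, np.repeat(np.arange(10), 3),
                                    ["intercept", "a", "a_copy"])


class TestNestedModels:
    def test_null_data_selects_null_mostly(self):
        rng = np.random.default_rng(11)
        wins = []
        for _ in range(30):
            fits = fit_nested_models(_cohort_frame(rng), ModelConfig())
            wins.append(select_best_model(fits, ModelConfig())[0])
        assert wins.count("null") >= 24  # large majority under the null

    def test_large_group_offset_selects_group(self):
        rng = np.random.default_rng(12)
        wins = []
        for _ in range(20):
            df = _cohort_frame(rng, group_offset=2.0, noise=1.0)  # 2 residual SDs
            fits = fit_nested_models(df, ModelConfig())
            wins.append(select_best_model(fits, ModelConfig())[0])
        assert wins.count("group") >= 16

    def test_trajectory_divergence_selects_interaction(self):
        rng = np.random.default_rng(13)
        df = _cohort_frame(rng, n_subj=120, age_slope_adhd=1.0, noise=1.0)
        fits = fit_nested_models(df, ModelConfig())
        assert select_best_model(fits, ModelConfig())[0] == "interaction"

    def test_single_group_marks_unavailable(self):
        rng = np.random.default_rng(14)
        df = _cohort_frame(rng)
        df = df[df.group == "control"]
        fits = fit_nested_models(df, ModelConfig())
        assert not fits["group"].available and not fits["interaction"].available
        assert select_best_model(fits, ModelConfig())[0] in ("null", "age")

    def test_aic_ordering_respects_nesting_loglik(self):
        rng = np.random.default_rng(15)
        fits = fit_nested_models(_cohort_frame(rng), ModelConfig())
        assert fits["age"].loglik >= fits["null"].loglik - 1e-6
        assert fits["interaction"].loglik >= fits["group"].loglik - 1e-6


def _fake_fit(name, aic, p=np.nan, available=True):
    return ModelFit(name=name, loglik=0.0, aic=aic, n_params=1, params=np.empty(0),
                    param_names=[], cov_params=np.empty((0, 0)), var_subject=0.0,
                    var_resid=1.0, p_term=p, available=available)


class TestSelectionRule:
    def test_margin_and_significance_worked_examples(self):
        cfg = ModelConfig()
        # delta = 2.1 with p = 0.01 -> age accepted
        fits = {"null": _fake_fit("null", 100.0), "age": _fake_fit("age", 97.9, 0.01)}
        assert select_best_model(fits, cfg)[0] == "age"
        # delta = 1.5 -> rejected regardless of p
        fits = {"null": _fake_fit("null", 100.0), "age": _fake_fit("age", 98.5, 1e-9)}
        assert select_best_model(fits, cfg)[0] == "null"
        # delta = 5 but p = 0.20 -> rejected
        fits = {"null": _fake_fit("null", 100.0), "age": _fake_fit("age", 95.0, 0.20)}
        assert select_best_model(fits, cfg)[0] == "null"

    def test_identical_aic_keeps_simpler(self):
        fits = {"null": _fake_fit("null", 100.0), "age": _fake_fit("age", 100.0, 0.001)}
        assert select_best_model(fits, ModelConfig())[0] == "null"

    def test_winner_must_beat_all_simpler_by_default(self):
        fits = {
            "null": _fake_fit("null", 100.0),
            "age": _fake_fit("age", 90.0, 0.001),
            "group": _fake_fit("group", 89.0, 0.001),  # beats null but not age
        }
        assert select_best_model(fits, ModelConfig())[0] == "age"
        # parent-only comparison flips it
        cfg = ModelConfig(compare_all_simpler=False)
        fits["group"] = _fake_fit("group", 87.0, 0.001)
        assert select_best_model(fits, cfg)[0] == "group"


class TestFdr:
    def test_hand_computed_bh_example(self):
        adj = fdr_correct({"a": 0.001, "b": 0.02, "c": 0.04}, q=0.05)
        assert adj["a"][0] == pytest.approx(0.003)
        assert adj["b"][0] == pytest.approx(0.03)
        assert adj["c"][0] == pytest.approx(0.04)
        assert all(sig for _, sig in adj.values())

    def test_all_ones_and_singleton(self):
        adj = fdr_correct({"a": 1.0, "b": 1.0}, q=0.05)
        assert not any(sig for _, sig in adj.values())
        adj = fdr_correct({"only": 0.04}, q=0.05)
        assert adj["only"] == (pytest.approx(0.04), True)

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(3)
        p = {f"r{i}": float(x) for i, x in enumerate(rng.uniform(size=40))}
        a1 = fdr_correct(p)
        a2 = fdr_correct(dict(reversed(list(p.items()))))
        assert a1 == a2
        ordered = sorted(p, key=p.get)
        qs = [a1[k][0] for k in ordered]
        assert all(x <= y + 1e-12 for x, y in zip(qs, qs[1:]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct({"a": 1.5})


class TestRegionwise:
    def test_row_count_and_permutation_invariance(self):
        rng = np.random.default_rng(4)
        frames = [
            _cohort_frame(np.random.default_rng(100 + r), n_subj=20, region=f"r{r}")
            for r in range(4)
        ]
        obs = pd.concat(frames, ignore_index=True)
        res1 = regionwise_analysis(obs, ModelConfig())
        assert len(res1) == 4
        shuffled = obs.sample(frac=1.0, random_state=rng.integers(1 << 30)).reset_index(drop=True)
        res2 = regionwise_analysis(shuffled, ModelConfig())
        pd.testing.assert_frame_equal(res1, res2)

    def test_q_value_at_least_p(self):
        obs = pd.concat(
            [_cohort_frame(np.random.default_rng(200 + r), n_subj=30,
                           group_offset=2.5 if r < 2 else 0.0, region=f"r{r}")
             for r in range(5)],
            ignore_index=True,
        )
        res = regionwise_analysis(obs, ModelConfig())
        sel = res[res.winner.isin(["group", "interaction"])]
        assert (sel.q_value >= sel.p_term - 1e-12).all()


class TestTrajectories:
    def test_null_fit_flat_and_group_fit_offset(self):
        rng = np.random.default_rng(5)
        df = _cohort_frame(rng, n_subj=80, group_offset=2.0)
        fits = fit_nested_models(df, ModelConfig())
        grid = np.linspace(10, 13, 5)
        null_curves = predict_trajectories(fits["null"], grid)
        piv = null_curves.pivot(index="age", columns="group", values="predicted")
        np.testing.assert_allclose(piv["ADHD"], piv["control"])  # no group term
        assert null_curves.predicted.std() < 1e-9  # flat in age
        grp_curves = predict_trajectories(fits["group"], grid)
        piv = grp_curves.pivot(index="age", columns="group", values="predicted")
        gaps = piv["ADHD"] - piv["control"]
        np.testing.assert_allclose(gaps, gaps.iloc[0])  # parallel curves
        assert gaps.iloc[0] == pytest.approx(2.0, abs=0.5)

    def test_interaction_fit_diverges_in_planted_direction(self):
        rng = np.random.default_rng(6)
        df = _cohort_frame(rng, n_subj=120, age_slope_adhd=1.0)
        fits = fit_nested_models(df, ModelConfig())
        curves = predict_trajectories(fits["interaction"], np.linspace(10, 13, 7))
        piv = curves.pivot(index="age", columns="group", values="predicted")
        gap = piv["ADHD"] - piv["control"]
        assert gap.iloc[-1] > gap.iloc[0]  # widening with age

    def test_extrapolation_flagged(self):
        rng = np.random.default_rng(7)
        fits = fit_nested_models(_cohort_frame(rng), ModelConfig())
        curves = predict_trajectories(fits["age"], np.array([5.0, 11.0, 20.0]))
        flagged = curves[curves.extrapolated].age.unique()
        assert set(flagged) == {5.0, 20.0}
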