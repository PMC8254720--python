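import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ponzopupil.simulate import SimulationConfig, simulate_summary_dataset
from ponzopupil.stats import (
    cell_means,
    context_effects,
    fit_lmm,
    lgbf_correlation,
    lgbf_ttest,
    median_split,
    partial_correlation,
    pearson_ci,
    run_full_inference,
    two_sample_bf_t,
)


def _balanced_table(rng, n_subj=8, reps=3, subj_sd=0.5, noise_sd=0.2,
                    size_slope=0.1, loc_shift=0.3, interaction=0.0,
                    center_subjects=False):
    rows = []
    noise = rng.normal(0, noise_sd, (n_subj, 5, 2, reps))
    if center_subjects:
        noise -= noise.reshape(n_subj, -1).mean(axis=1)[:, None, None, None]
    intercepts = rng.normal(0, subj_sd, n_subj)
    for s in range(n_subj):
        for i, size in enumerate(range(1, 6)):
            for j, loc in enumerate(("near", "far")):
                for r in range(reps):
                    y = (size_slope * size + loc_shift * (loc == "far")
                         + interaction * size * (loc == "far")
                         + intercepts[s] + noise[s, i, j, r])
                    rows.append({"participant_id": s, "size_level": size,
                                 "location": loc, "y": y})
    return pd.DataFrame(rows)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0)

    def test_printed_pairs_closed_form(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 6.0])
        res = pearson_ci(x, y)
        # hand-computed covariance ratio
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_ci_contains_r(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = pearson_ci(x, y)
        assert res.ci95[0] <= res.r <= res.ci95[1]

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson_ci([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_type1_error_quick(self):
        hits = 0
        n_sims = 400
        rng = np.random.default_rng(0)
        for _ in range(n_sims):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            hits += pearson_ci(x, y).p < 0.05
        assert 0.02 < hits / n_sims < 0.09


class TestLgbfCorrelation:
    def test_null_at_n50_is_substantial_h0(self):
        assert lgbf_correlation(0.0, 50) < -0.5

    def test_headline_value_crosses_threshold(self):
        assert lgbf_correlation(0.38, 50) > 0.5

    def test_symmetry(self):
        for r in (0.1, 0.3, 0.7, 0.95):
            for n in (10, 30, 80):
                assert lgbf_correlation(r, n) == pytest.approx(
                    lgbf_correlation(-r, n), abs=1e-10
                )

    def test_monotone_in_abs_r(self):
        for n in (10, 50):
            vals = [lgbf_correlation(r, n) for r in np.linspace(0, 0.95, 15)]
            assert np.all(np.diff(vals) > 0)

    def test_decreasing_in_n_at_null(self):
        vals = [lgbf_correlation(0.0, n) for n in (10, 20, 50, 100, 200)]
        assert np.all(np.diff(vals) < 0)

    def test_finite_at_small_n(self):
        assert np.isfinite(lgbf_correlation(0.5, 3))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            lgbf_correlation(1.5, 50)
        with pytest.raises(ValueError):
            lgbf_correlation(0.2, 2)


class TestPartialCorrelation:
    def test_orthogonal_covariate_leaves_r(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        z = rng.normal(size=200)
        # orthogonalize z jointly against [1, x, y]
        basis = np.column_stack([np.ones(200), x, y])
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        plain = pearson_ci(x, y).r
        partial = partial_correlation(x, y, z).r
        assert partial == pytest.approx(plain, abs=1e-10)

    def test_shared_cause_removed(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(1000):
            z = rng.normal(size=60)
            x = z + rng.normal(size=60)
            y = z + rng.normal(size=60)
            rs.append(partial_correlation(x, y, z).r)
        assert abs(np.mean(rs)) < 0.05

    def test_textbook_formula_six_points(self):
        x = np.array([1.0, 2, 3, 5, 8, 9])
        y = np.array([2.0, 1, 5, 4, 9, 8])
        z = np.array([1.0, 1, 2, 3, 5, 5])
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_correlation(x, y, z).r == pytest.approx(expected, abs=1e-10)

    def test_deterministic_function_of_z(self, rng):
        z = rng.normal(size=50)
        y = 3 * z - 1
        x = rng.normal(size=50)
        res = partial_correlation(x, y, z)
        assert res.r == 0.0
        assert res.p == 1.0


class TestLmm:
    def test_zero_variance_limit_matches_anova(self, rng):
        df = _balanced_table(rng, subj_sd=0.0, center_subjects=True,
                             interaction=0.05)
        res = fit_lmm(df, "y", ["size_level", "location", "size_level:location"])
        assert res.tau2 == 0.0
        # classical two-way ANOVA oracle from explicit sums of squares
        y = df["y"].to_numpy()
        ga = y.mean()
        A = df.groupby("size_level")["y"].mean()
        B = df.groupby("location")["y"].mean()
        nA, nB = 5, 2
        n_per_a = len(y) / nA
        n_per_b = len(y) / nB
        n_per_cell = len(y) / (nA * nB)
        SSA = n_per_a * ((A - ga) ** 2).sum()
        SSB = n_per_b * ((B - ga) ** 2).sum()
        cell = df.groupby(["size_level", "location"])["y"].mean()
        SSAB = n_per_cell * sum(
            (cell[a, b] - A[a] - B[b] + ga) ** 2
            for a in A.index for b in B.index
        )
        fitted = df.groupby(["size_level", "location"])["y"].transform("mean")
        SSE = ((y - fitted) ** 2).sum()
        dfe = len(y) - nA * nB
        mse = SSE / dfe
        for name, (ss, q) in {"size_level": (SSA, 4), "location": (SSB, 1),
                              "size_level:location": (SSAB, 4)}.items():
            term = res.terms[name]
            assert term.df_num == q
            assert term.df_den == dfe
            assert term.F == pytest.approx(ss / q / mse, rel=1e-6)

    def test_matches_statsmodels_variance_components(self, rng):
        sm = pytest.importorskip("statsmodels.formula.api")
        df = _balanced_table(rng, subj_sd=0.6)
        res = fit_lmm(df, "y", ["size_level", "location"])
        fit = sm.mixedlm("y ~ C(size_level, Sum) + C(location, Sum)", df,
                         groups=df["participant_id"]).fit(reml=True)
        assert res.sigma2 == pytest.approx(float(fit.scale), rel=1e-3)
        assert res.tau2 == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-2)

    def test_planted_location_shift_power(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            df = _balanced_table(rng, n_subj=20, reps=5, subj_sd=0.3,
                                 noise_sd=0.1, loc_shift=0.1, size_slope=0.0)
            res = fit_lmm(df, "y", ["size_level", "location"])
            hits += res.terms["location"].p < 0.001
        assert hits >= 57  # >=95%

    def test_permuted_response_uniform_p(self):
        rng = np.random.default_rng(3)
        df = _balanced_table(rng, n_subj=6, reps=2, subj_sd=0.0, noise_sd=1.0,
                             size_slope=0.0, loc_shift=0.0)
        ps = {"size_level": [], "location": []}
        y = df["y"].to_numpy()
        for _ in range(200):
            df["y"] = rng.permutation(y)
            res = fit_lmm(df, "y", ["size_level", "location"])
            for k in ps:
                ps[k].append(res.terms[k].p)
        for k, vals in ps.items():
            assert sps.kstest(vals, "uniform").pvalue > 0.01

    def test_singular_design_raises_with_factor_name(self, rng):
        df = _balanced_table(rng)
        df = df[df["location"] == "near"]
        with pytest.raises(ValueError, match="location"):
            fit_lmm(df, "y", ["size_level", "location"])

    def test_deterministic(self, rng):
        df = _balanced_table(rng)
        a = fit_lmm(df, "y", ["size_level", "location"])
        b = fit_lmm(df, "y", ["size_level", "location"])
        assert a.terms["location"].F == b.terms["location"].F

    def test_numeric_covariate_interaction(self, rng):
        df = _balanced_table(rng)
        df["aq"] = df["participant_id"].map(
            {s: 2 + 3 * s for s in df["participant_id"].unique()}
        )
        res = fit_lmm(df, "y", ["aq", "location", "aq:location"])
        assert set(res.terms) == {"aq", "location", "aq:location"}
        assert all(t.F >= 0 for t in res.terms.values())


def _toy_trials():
    rows = []
    for pid, far_val, near_val in (("a", -0.3, -0.2), ("b", -0.5, -0.1)):
        for size in range(1, 6):
            for loc, val in (("far", far_val), ("near", near_val)):
                rows.append({"participant_id": pid, "size_level": size,
                             "location": loc, "pupil_response_mm": val,
                             "report_mm": 80.0 + (loc == "far") * 5,
                             "baseline_pupil_mm": 4.2, "gaze_x_deg": 0.0,
                             "gaze_y_deg": 0.0, "valid": True})
    return pd.DataFrame(rows)


class TestContextEffects:
    def test_constant_trials_zero_effects(self):
        df = _toy_trials()
        df["pupil_response_mm"] = -0.25
        eff = context_effects(df)
        np.testing.assert_allclose(eff["pupil_far_minus_near"], 0.0)

    def test_far_near_arithmetic(self):
        eff = context_effects(_toy_trials()).set_index("participant_id")
        assert eff.loc["a", "pupil_far_minus_near"] == pytest.approx(-0.1)
        assert eff.loc["b", "pupil_far_minus_near"] == pytest.approx(-0.4)
        assert eff.loc["a", "report_far_minus_near"] == pytest.approx(5.0)

    def test_per_size_effects_average_to_pooled_on_balanced(self):
        eff = context_effects(_toy_trials())
        per_size = eff[[f"pupil_far_minus_near_size{s}" for s in range(1, 6)]]
        np.testing.assert_allclose(per_size.mean(axis=1),
                                   eff["pupil_far_minus_near"])

    def test_random_masks_vs_oracle(self, rng):
        df = _toy_trials()
        df["pupil_response_mm"] = rng.normal(size=len(df))
        df["valid"] = rng.random(len(df)) > 0.3
        eff = context_effects(df).set_index("participant_id")
        for pid in ("a", "b"):
            sub = df[(df["participant_id"] == pid) & df["valid"]]
            far = sub[sub["location"] == "far"]["pupil_response_mm"]
            near = sub[sub["location"] == "near"]["pupil_response_mm"]
            if len(far) and len(near):
                assert eff.loc[pid, "pupil_far_minus_near"] == pytest.approx(
                    far.mean() - near.mean()
                )
            else:
                assert np.isnan(eff.loc[pid, "pupil_far_minus_near"])

    def test_missing_cell_yields_nan(self):
        df = _toy_trials()
        df.loc[(df["participant_id"] == "a") & (df["location"] == "far"),
               "valid"] = False
        eff = context_effects(df).set_index("participant_id")
        assert np.isnan(eff.loc["a", "pupil_far_minus_near"])
        assert np.isfinite(eff.loc["b", "pupil_far_minus_near"])

    def test_cell_means_max_10_per_participant(self):
        cells = cell_means(_toy_trials())
        assert cells.groupby("participant_id").size().max() == 10


class TestMedianSplit:
    def _effects(self, aqs, values):
        return pd.DataFrame({"participant_id": range(len(aqs)), "aq": aqs,
                             "pupil_far_minus_near": values})

    def test_ties_go_to_low_group(self):
        aqs = list(range(2, 32))  # median 16.5 -> use explicit tie case
        eff = self._effects([10, 16, 16, 20, 25, 3],
                            [-0.1, -0.2, -0.3, 0.0, 0.1, -0.4])
        out = median_split(eff, "pupil_far_minus_near")
        assert out["aq_median"] == 16.0
        assert out["low"]["n"] == 4  # both 16s in the low group
        assert out["high"]["n"] == 2

    def test_degenerate_equal_effects(self):
        eff = self._effects([5, 10, 20, 25], [-0.1] * 4)
        out = median_split(eff, "pupil_far_minus_near")
        for grp in ("low", "high"):
            assert out[grp]["mean"] == pytest.approx(-0.1)
            assert out[grp]["ci95"][0] == pytest.approx(out[grp]["ci95"][1])

    def test_brute_force_group_means(self, rng):
        aqs = rng.integers(2, 32, 20)
        vals = rng.normal(size=20)
        eff = self._effects(aqs, vals)
        out = median_split(eff, "pupil_far_minus_near")
        med = np.median(aqs)
        assert out["low"]["mean"] == pytest.approx(vals[aqs <= med].mean())
        assert out["high"]["mean"] == pytest.approx(vals[aqs > med].mean())

    def test_small_group_raises(self):
        eff = self._effects([5, 20, 21], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            median_split(eff, "pupil_far_minus_near")


class TestTwoSampleBF:
    def test_identical_groups(self):
        a = np.array([1.0, 2, 3, 4])
        res = two_sample_bf_t(a, a.copy())
        assert res.t == 0.0
        assert res.lgbf < 0

    def test_toy_table_closed_form(self):
        a = np.array([5.0, 6, 7, 8, 9])
        b = np.array([3.0, 4, 5, 6, 7])
        res = two_sample_bf_t(a, b)
        sp2 = (a.var(ddof=1) * 4 + b.var(ddof=1) * 4) / 8
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 5))
        assert res.t == pytest.approx(t_expected, abs=1e-12)
        assert res.df == 8

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, n1, n2, scale in ((0.18, 33, 17, 0.707), (2.2, 25, 25, 1.0)):
            ref = float(np.log10(float(pg.bayesfactor_ttest(t, n1, n2, r=scale))))
            assert lgbf_ttest(t, n1, n2, r_scale=scale) == pytest.approx(
                ref, abs=1e-8
            )

    def test_planted_shift_detected(self):
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            a = rng.normal(2.0, 1.0, 17)
            b = rng.normal(0.0, 1.0, 33)
            hits += two_sample_bf_t(a, b).lgbf > 0.5
        assert hits >= 95

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            two_sample_bf_t([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def dataset():
    cfg = SimulationConfig(n_participants=24, seed=21)
    return simulate_summary_dataset(cfg)


class TestRunFullInference:

    def test_bundle_completeness(self, dataset):
        trials, participants = dataset
        bundle = run_full_inference(trials, participants)
        assert {"lmm", "correlations", "median_split", "gender",
                "pupil_vs_report"} <= set(bundle)
        assert "baseline_size_location" in bundle["lmm"]
        assert "gaze_x_size_location" in bundle["lmm"]
        assert "pupil_effect_vs_aq" in bundle["correlations"]
        assert bundle["cells_per_participant_max"] == 10

    def test_deterministic_rerun(self, dataset):
        trials, participants = dataset
        a = run_full_inference(trials, participants)
        b = run_full_inference(trials.copy(), participants.copy())
        assert a == b

    def test_participant_without_far_trials_dropped_and_logged(self, dataset):
        trials, participants = dataset
        trials = trials.copy()
        pid = trials["participant_id"].iloc[0]
        mask = (trials["participant_id"] == pid) & (trials["location"] == "far")
        trials.loc[mask, "valid"] = False
        bundle = run_full_inference(trials, participants)
        assert pid in bundle["participants_without_effects"]
        n = bundle["correlations"]["pupil_effect_vs_aq"]["n"]
        assert n == participants["participant_id"].nunique() - 1
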