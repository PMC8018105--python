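import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epirelapse.errors import ValidationError
from epirelapse.diffmeth import (
    adjust_pvalues,
    dmp_from_differences,
    make_pairs,
    moderate_variances,
    paired_differences,
    paired_t,
    run_dmp,
)
from epirelapse.io_model import SampleSheet, align_inputs
from epirelapse.synthetic import SimulationConfig, simulate_dataset


def _sheet(rows):
    df = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "status", "relapse_index", "subgroup"]
    ).set_index("sample_id")
    return SampleSheet(df)


class TestMakePairs:
    def test_one_primary_one_relapse(self):
        pairs = make_pairs(
            _sheet([("a", "p1", "PRIMARY", 0, "g"), ("b", "p1", "RELAPSE", 1, "g")])
        )
        assert len(pairs) == 1
        assert pairs[0].primary_sample == "a"
        assert pairs[0].relapse_samples == ("b",)

    def test_first_relapse_picks_lowest_index(self):
        pairs = make_pairs(
            _sheet(
                [
                    ("a", "p1", "PRIMARY", 0, "g"),
                    ("c", "p1", "RELAPSE", 2, "g"),
                    ("b", "p1", "RELAPSE", 1, "g"),
                ]
            )
        )
        assert pairs[0].relapse_samples == ("b",)

    def test_averaged_policy_uses_mean_of_relapses(self):
        sheet = _sheet(
            [
                ("a", "p1", "PRIMARY", 0, "g"),
                ("b", "p1", "RELAPSE", 1, "g"),
                ("c", "p1", "RELAPSE", 2, "g"),
                ("d", "p1", "RELAPSE", 3, "g"),
            ]
        )
        pairs = make_pairs(sheet, "all_relapses_averaged")
        vals = pd.DataFrame(
            {"a": [1.0], "b": [2.0], "c": [4.0], "d": [6.0]},
            index=pd.Index(["cg1"], name="probe_id"),
        )
        d = paired_differences(vals, pairs)
        assert d.loc["cg1", "p1"] == pytest.approx((2 + 4 + 6) / 3 - 1)

    def test_relapse_only_patient_dropped(self):
        pairs = make_pairs(
            _sheet(
                [
                    ("a", "p1", "PRIMARY", 0, "g"),
                    ("b", "p1", "RELAPSE", 1, "g"),
                    ("c", "p2", "RELAPSE", 1, "g"),
                ]
            )
        )
        assert [p.patient_id for p in pairs] == ["p1"]

    def test_no_pairs_rejected(self):
        with pytest.raises(ValidationError):
            make_pairs(_sheet([("a", "p1", "PRIMARY", 0, "g")]))


class TestPairedT:
    def test_all_zero_differences(self):
        logfc, t, df, p = paired_t(np.zeros(3))
        assert (logfc, t, df, p) == (0.0, 0.0, 2.0, 1.0)

    def test_frozen_example(self):
        logfc, t, df, p = paired_t(np.array([1.0, 2.0, 3.0]))
        assert logfc == pytest.approx(2.0)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        # closed form for df=2: P(T<=t) = 1/2 + t/(2*sqrt(2+t^2))
        p_exact = 2 * (1 - (0.5 + t / (2 * np.sqrt(2 + t**2))))
        assert p == pytest.approx(p_exact, abs=1e-12)
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_sign_antisymmetry(self):
        _, t1, _, p1 = paired_t(np.array([1.0, 2.0, 3.0]))
        _, t2, _, p2 = paired_t(np.array([-1.0, -2.0, -3.0]))
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_vectorized_matches_scalar_and_handles_nan(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(0, 1, (20, 8))
        mat[0, :3] = np.nan
        mat[1, :] = np.nan
        logfc, t, df, p = paired_t(mat)
        row0 = mat[0][~np.isnan(mat[0])]
        _, t0, df0, p0 = paired_t(row0)
        assert t[0] == pytest.approx(t0) and df[0] == df0 and p[0] == pytest.approx(p0)
        assert np.isnan(t[1]) and np.isnan(p[1])

    def test_too_few_differences_rejected(self):
        with pytest.raises(ValidationError):
            paired_t(np.array([1.0]))

    def test_sign_flip_permutation_oracle(self):
        """t-tail p tracks the exact sign-flip randomization p in aggregate."""
        rng = np.random.default_rng(42)
        diffs_p, min_hits = [], 0
        n_small_p = 0
        for _ in range(120):
            n = int(rng.integers(4, 11))
            d = rng.normal(rng.normal(0, 0.9), 1.0, n)
            _, t_obs, _, p_t = paired_t(d)
            signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
            flipped = signs * d
            m = flipped.mean(axis=1)
            s = flipped.std(ddof=1, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm = np.where(s > 0, m / (s / np.sqrt(n)), 0.0)
            p_perm = float(np.mean(np.abs(t_perm) >= abs(t_obs) - 1e-12))
            diffs_p.append(abs(p_t - p_perm))
            if p_t < 0.005:
                n_small_p += 1
                # randomization p must sit in the bottom few achievable
                # values (floor 2/2^n, granularity 1/2^n)
                if p_perm <= 8.0 / 2**n + 1e-12:
                    min_hits += 1
        assert np.mean(diffs_p) < 0.05
        assert n_small_p > 5 and min_hits == n_small_p


class TestModerateVariances:
    def test_equal_variances_collapse_to_common_value(self):
        s2 = np.full(50, 0.7)
        d0, s0sq, post = moderate_variances(s2, np.full(50, 10.0))
        assert np.isinf(d0)
        assert s0sq == pytest.approx(0.7)
        assert post == pytest.approx(np.full(50, 0.7))

    def test_posterior_bounded_by_raw_and_prior(self):
        rng = np.random.default_rng(5)
        df = 8.0
        s2 = rng.chisquare(df, 500) / df
        d0, s0sq, post = moderate_variances(s2, np.full(500, df))
        lo = np.minimum(s2, s0sq)
        hi = np.maximum(s2, s0sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_parameter_recovery(self):
        """Moment matching recovers (d0, s0^2) from data generated under the model."""
        rng = np.random.default_rng(7)
        d0_true, s0sq_true, df = 4.0, 1.0, 10.0
        sigma2 = s0sq_true * d0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(df, 5000) / df
        d0, s0sq, _ = moderate_variances(s2, np.full(5000, df))
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0sq == pytest.approx(s0sq_true, rel=0.10)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValidationError):
            moderate_variances(np.zeros(20), np.full(20, 5.0))


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_frozen_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_stay_equal(self):
        out = adjust_pvalues([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, out[0])

    def test_matches_direct_step_up_formula(self):
        """Independent oracle: BH computed directly from its definition."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            order = np.argsort(p)
            adj_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            assert adjust_pvalues(p) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(13)
        p = rng.random(30)
        perm = rng.permutation(30)
        assert adjust_pvalues(p)[perm] == pytest.approx(adjust_pvalues(p[perm]))
        bumped = p.copy()
        bumped[4] = min(1.0, bumped[4] + 0.2)
        assert (adjust_pvalues(bumped) >= adjust_pvalues(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


class TestRunDmp:
    def test_null_type_one_error_calibrated(self):
        cfg = SimulationConfig(
            n_probes=20_000,
            subgroups=(("g", 20),),
            delta_island={},
            delta_shelf={},
            seed=101,
        )
        ds = simulate_dataset(cfg)
        al = align_inputs(ds.annotation, ds.beta, ds.sheet)
        tab = run_dmp(al).table
        frac = float((tab["p_raw"] < 0.05).mean())
        assert 0.04 < frac < 0.06

    def test_planted_effect_shifts_p_distribution(self):
        cfg = SimulationConfig(n_probes=4000, subgroups=(("g", 20),),
                               delta_island={"g": 0.05}, delta_shelf={}, seed=23)
        ds = simulate_dataset(cfg)
        al = align_inputs(ds.annotation, ds.beta, ds.sheet)
        tab = run_dmp(al).table
        affected = ds.truth.beta_shift["g"] > 0
        assert tab.loc[affected, "p_raw"].median() < tab.loc[~affected, "p_raw"].median()

    def test_tiny_subgroup_runs_with_df_one(self):
        cfg = SimulationConfig(n_probes=300, subgroups=(("PF-SE", 2),), seed=3)
        ds = simulate_dataset(cfg)
        al = align_inputs(ds.annotation, ds.beta, ds.sheet)
        tabs = run_dmp(al, "per_subgroup")
        t = tabs["PF-SE"].table
        assert (t["df"].dropna() == 1).all()
        assert t["p_raw"].between(0, 1).all()

    def test_single_pair_subgroup_yields_empty_table(self):
        cfg = SimulationConfig(n_probes=200, subgroups=(("solo", 1), ("g", 3)), seed=4)
        ds = simulate_dataset(cfg)
        al = align_inputs(ds.annotation, ds.beta, ds.sheet)
        tabs = run_dmp(al, "per_subgroup")
        assert len(tabs["solo"].table) == 0
        assert len(tabs["g"].table) == 200

    def test_moderation_preserves_logfc_and_shrinks_t_spread(self, small_aligned):
        plain = run_dmp(small_aligned).table
        mod = run_dmp(small_aligned, moderation=True).table
        assert mod["logFC"].to_numpy() == pytest.approx(plain["logFC"].to_numpy())
        # moderated df strictly larger; t spread no larger than raw for null-ish probes
        assert (mod["df"].dropna() > plain["df"].dropna()).all()
        assert mod["p_raw"].between(0, 1).all()

    def test_adjusted_at_least_raw_minimum(self, small_aligned):
        tab = run_dmp(small_aligned).table
        assert tab["p_adj"].min() >= tab["p_raw"].min() - 1e-15
        nz = (tab["t_stat"] != 0) & (tab["logFC"] != 0)
        assert (np.sign(tab.loc[nz, "t_stat"]) == np.sign(tab.loc[nz, "logFC"])).all()
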