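import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ccsdelta.io import DataError
from ccsdelta.stats import (
    attach_residuals,
    benjamini_hochberg,
    charge_state_profile,
    deltaccs_gradient,
    deltaccs_mass_correlation,
    fit_ion_cloud,
    rank_concordance,
    summarize_modifications,
    wilcoxon_one_sample,
)


def brute_force_wilcoxon(values):
    """Two-sided exact signed-rank p by full 2^n sign-flip enumeration."""
    values = np.asarray(values, dtype=float)
    nz = values[values != 0]
    n = nz.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_oracle(p):
    """Naive sort / adjust / cumulative-min reimplementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = np.inf
    for i in range(m - 1, -1, -1):
        val = min(prev, p[order[i]] * m / (i + 1))
        q[order[i]] = min(val, 1.0)
        prev = val
    return q


def make_pairs(name, deltas, charge=2, ccs_unmod=500.0, sequences=None):
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    if sequences is None:
        sequences = [f"SEQ{i:03d}K" for i in range(n)]
    return pd.DataFrame(
        {
            "sequence": sequences,
            "modification_name": name,
            "mod_position": 3,
            "charge": charge,
            "ccs_modified": ccs_unmod * (1 + deltas),
            "ccs_unmodified": ccs_unmod,
            "delta_ccs_rel": deltas,
            "delta_ccs_abs": ccs_unmod * deltas,
            "delta_rt": 0.0,
            "delta_mass": 42.0,
        }
    )


class TestWilcoxon:
    def test_all_positive_extreme_exact_p(self):
        # W+ at its maximum; exact two-sided p = 2 * (1/32)
        assert wilcoxon_one_sample([1, 2, 3, 4, 5]) == pytest.approx(2 / 32)

    def test_symmetric_values_match_brute_force(self):
        vals = [-1, 1, -2, 2]
        assert wilcoxon_one_sample(vals) == pytest.approx(brute_force_wilcoxon(vals))

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 11))
            vals = np.round(rng.normal(0.3, 1.0, n), 2)
            assert wilcoxon_one_sample(vals) == pytest.approx(
                brute_force_wilcoxon(vals), abs=1e-12
            )

    def test_all_zeros_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="mu0"):
            assert wilcoxon_one_sample([0.0, 0.0]) == 1.0

    def test_mu0_shifts_the_null(self):
        vals = [5.1, 5.2, 4.9, 5.0, 5.3]
        assert wilcoxon_one_sample(vals, mu0=5.0) == pytest.approx(
            brute_force_wilcoxon(np.asarray(vals) - 5.0)
        )

    def test_large_n_close_to_scipy_normal_approximation(self, rng):
        vals = rng.normal(0.2, 1.0, 60)
        ours = wilcoxon_one_sample(vals)
        ref = sps.wilcoxon(vals, correction=True, mode="approx").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.1] * 5), [0.1] * 5)

    def test_matches_naive_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 30)))
            np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_input_order_preserved(self, rng):
        p = rng.uniform(0, 1, 10)
        q = benjamini_hochberg(p)
        perm = rng.permutation(10)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), q[perm])


class TestSummarizeModifications:
    def test_all_zero_deltas(self):
        pairs = make_pairs("Acetyl (K)", np.zeros(10))
        out = summarize_modifications(pairs)
        assert out.loc[0, "med"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_null_and_shifted_modifications_ranked_by_bh(self, rng):
        null = make_pairs("NullMod (K)", rng.normal(0.0, 0.01, 40))
        shifted = make_pairs("ShiftMod (K)", rng.normal(0.045, 0.01, 40))
        out = summarize_modifications(pd.concat([null, shifted], ignore_index=True))
        out = out.set_index("modification_name")
        assert out.loc["ShiftMod (K)", "q_value"] < out.loc["NullMod (K)", "q_value"]
        assert out.loc["ShiftMod (K)", "q_value"] < 0.05

    def test_med_is_percent_and_within_delta_range(self, rng):
        deltas = rng.normal(0.043, 0.01, 80)
        out = summarize_modifications(make_pairs("Biotinyl (K)", deltas))
        assert out.loc[0, "med"] == pytest.approx(100 * np.median(deltas))
        assert 100 * deltas.min() <= out.loc[0, "med"] <= 100 * deltas.max()

    def test_charge_counts(self):
        pairs = pd.concat(
            [make_pairs("M (K)", [0.01] * 3, charge=2),
             make_pairs("M (K)", [0.02] * 2, charge=3)],
            ignore_index=True,
        )
        out = summarize_modifications(pairs)
        assert out.loc[0, "n_pairs_z2"] == 3
        assert out.loc[0, "n_pairs_z3"] == 2
        assert out.loc[0, "n_pairs_total"] == 5

    def test_empty_errors(self):
        with pytest.raises(DataError):
            summarize_modifications(make_pairs("M", []))


class TestChargeProfile:
    def _records(self, counts, name="Unmodified", seq="PEPTKIDE"):
        rows = []
        for z, n in counts.items():
            for i in range(n):
                rows.append(
                    {"modification_name": name, "charge": z,
                     "sequence": seq, "modified_sequence": f"{seq}{z}{i}",
                     "intensity_max": 10.0}
                )
        return pd.DataFrame(rows)

    def test_fractions_and_predominant(self):
        out = charge_state_profile(self._records({2: 74, 3: 26}))
        out = out.set_index("charge")
        assert out.loc[2, "fraction"] == pytest.approx(0.74)
        assert out.loc[3, "fraction"] == pytest.approx(0.26)
        assert (out["predominant_charge"] == 2).all()

    def test_tie_goes_to_lower_charge(self):
        out = charge_state_profile(self._records({2: 10, 3: 10}))
        assert (out["predominant_charge"] == 2).all()

    def test_fractions_sum_to_one(self, rng):
        out = charge_state_profile(self._records({2: 7, 3: 5, 4: 1}))
        assert out["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_predominant_stable_under_duplication(self):
        rec = self._records({2: 3, 3: 5})
        doubled = pd.concat([rec, rec], ignore_index=True)
        a = charge_state_profile(rec)
        b = charge_state_profile(doubled)
        assert a["predominant_charge"].iloc[0] == b["predominant_charge"].iloc[0]

    def test_internal_residue_filter_boundary(self):
        kept = charge_state_profile(
            self._records({2: 1}, seq="PEPTKIDE"), internal_residue_filter={"K"}
        )
        dropped = charge_state_profile(
            self._records({2: 1}, seq="PEPTIDEK"), internal_residue_filter={"K"}
        )
        assert len(kept) == 1
        assert dropped.empty


class TestIonCloud:
    def _records(self, mz, ccs, charge=2):
        return pd.DataFrame(
            {
                "sequence": [f"S{i}K" for i in range(len(mz))],
                "charge": charge,
                "mz": mz,
                "ccs_mean": ccs,
            }
        )

    def test_collinear_records_zero_residuals(self):
        mz = np.array([400.0, 500.0, 600.0, 700.0])
        rec = self._records(mz, 150.0 + 0.5 * mz)
        fit = fit_ion_cloud(rec, 2)
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(150.0)
        np.testing.assert_allclose(fit.residuals["residual"], 0.0, atol=1e-9)

    def test_residuals_sum_to_zero(self, rng):
        rec = self._records(
            rng.uniform(400, 800, 50), rng.uniform(350, 650, 50)
        )
        fit = fit_ion_cloud(rec, 2)
        assert fit.residuals["residual"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_known_slope_recovered(self, rng):
        mz = rng.uniform(400, 800, 200)
        ccs = 140.0 + 0.55 * mz + rng.normal(0, 15.0, 200)
        fit = fit_ion_cloud(self._records(mz, ccs), 2)
        se = 15.0 / np.sqrt(((mz - mz.mean()) ** 2).sum())
        assert abs(fit.slope - 0.55) < 3 * se

    def test_too_few_records(self):
        with pytest.raises(DataError, match=">= 3"):
            fit_ion_cloud(self._records([400.0, 500.0], [300.0, 350.0]), 2)


class TestGradient:
    def _pairs_with_residuals(self, residuals, dccs_abs, name="Succinyl (K)"):
        pairs = make_pairs(name, np.asarray(dccs_abs) / 500.0)
        pairs["delta_ccs_abs"] = dccs_abs
        pairs["residual_unmodified"] = residuals
        return pairs

    def test_constant_shift_zero_slope(self):
        p = self._pairs_with_residuals([-10.0, 0.0, 10.0, 20.0], [5.0] * 4)
        g = deltaccs_gradient(p)
        assert g.gradient_slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation(self):
        resid = np.array([-20.0, -5.0, 0.0, 10.0, 30.0])
        p = self._pairs_with_residuals(resid, -0.3 * resid + 5.0)
        g = deltaccs_gradient(p)
        assert g.gradient_slope == pytest.approx(-0.3, rel=1e-12)
        assert g.intercept == pytest.approx(5.0, rel=1e-12)
        assert g.standard_error == pytest.approx(0.0, abs=1e-10)

    def test_slope_invariant_under_constant_offsets(self, rng):
        resid = rng.normal(0, 15, 50)
        y = -0.3 * resid + rng.normal(0, 2, 50)
        base = deltaccs_gradient(self._pairs_with_residuals(resid, y))
        shifted_y = deltaccs_gradient(self._pairs_with_residuals(resid, y + 7.0))
        shifted_x = deltaccs_gradient(self._pairs_with_residuals(resid + 11.0, y))
        assert shifted_y.gradient_slope == pytest.approx(base.gradient_slope, rel=1e-9)
        assert shifted_x.gradient_slope == pytest.approx(base.gradient_slope, rel=1e-9)

    def test_insufficient_pairs_returns_none_with_warning(self):
        p = self._pairs_with_residuals([1.0, 2.0], [0.1, 0.2])
        with pytest.warns(UserWarning):
            assert deltaccs_gradient(p) is None

    def test_relative_mode(self):
        resid = np.array([-20.0, 0.0, 20.0, 40.0])
        p = self._pairs_with_residuals(resid, -0.3 * resid)
        g = deltaccs_gradient(p, mode="relative")
        assert g.gradient_slope == pytest.approx(-0.3 / 500.0, rel=1e-9)

    def test_attach_residuals(self):
        pairs = make_pairs("Succinyl (K)", [0.01, 0.02], sequences=["AAK", "BBK"])
        cloud_rec = pd.DataFrame(
            {"sequence": ["AAK", "BBK", "CCK"], "charge": 2,
             "mz": [400.0, 500.0, 600.0], "ccs_mean": [340.0, 400.0, 440.0]}
        )
        fit = fit_ion_cloud(cloud_rec, 2)
        out = attach_residuals(pairs, [fit])
        lookup = dict(zip(fit.residuals["sequence"], fit.residuals["residual"]))
        assert out.loc[0, "residual_unmodified"] == pytest.approx(lookup["AAK"])


class TestCorrelation:
    def _summary(self, med, dm):
        return pd.DataFrame(
            {
                "modification_name": [f"M{i}" for i in range(len(med))],
                "med": med,
                "delta_mass": dm,
                "median_delta_rt": 0.0,
            }
        )

    def test_perfect_linearity(self):
        dm = np.array([10.0, 50.0, 100.0, 200.0])
        res = deltaccs_mass_correlation(self._summary(0.02 * dm, dm))
        assert res.r_squared == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        dm = rng.uniform(10, 200, 200)
        med = rng.permutation(0.02 * dm)
        res = deltaccs_mass_correlation(self._summary(med, dm))
        assert res.r_squared < 0.1

    def test_excluding_heavy_tail_reduces_r_squared(self, rng):
        dm = np.array([10, 20, 30, 40, 50, 60, 200.0, 230.0])
        med = 0.3 * rng.normal(size=8)
        med[-2:] = 0.02 * dm[-2:]  # only the heavy points carry the trend
        full = deltaccs_mass_correlation(self._summary(med, dm))
        trimmed = deltaccs_mass_correlation(
            self._summary(med, dm), exclude=("M6", "M7")
        )
        assert trimmed.r_squared < full.r_squared
        assert trimmed.exclusions == ("M6", "M7")

    def test_too_few_points(self):
        with pytest.raises(DataError):
            deltaccs_mass_correlation(self._summary([1.0, 2.0], [10.0, 20.0]))


class TestRankConcordance:
    def test_constant_shift_gives_rho_one(self, rng):
        seqs = [f"S{i}K" for i in range(10)]
        base = rng.normal(0, 10, 10)
        a = make_pairs("A (K)", base / 500.0, sequences=seqs)
        a["delta_ccs_abs"] = base
        b = make_pairs("B (K)", (base + 7.0) / 500.0, sequences=seqs)
        b["delta_ccs_abs"] = base + 7.0
        rho, n = rank_concordance(a, b)
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_reversed_ranks_give_minus_one(self, rng):
        seqs = [f"S{i}K" for i in range(8)]
        vals = np.arange(8, dtype=float)
        a = make_pairs("A (K)", vals / 500.0, sequences=seqs)
        a["delta_ccs_abs"] = vals
        b = make_pairs("B (K)", vals[::-1] / 500.0, sequences=seqs)
        b["delta_ccs_abs"] = vals[::-1]
        rho, _ = rank_concordance(a, b)
        assert rho == pytest.approx(-1.0)

    def test_rho_decreases_with_noise(self, rng):
        seqs = [f"S{i}K" for i in range(60)]
        shared = rng.normal(0, 15, 60)
        rhos = []
        for sd in (1.0, 8.0, 40.0):
            a = make_pairs("A (K)", shared / 500.0, sequences=seqs)
            a["delta_ccs_abs"] = shared + rng.normal(0, sd, 60)
            b = make_pairs("B (K)", shared / 500.0, sequences=seqs)
            b["delta_ccs_abs"] = shared + rng.normal(0, sd, 60)
            rhos.append(rank_concordance(a, b)[0])
        assert rhos[0] > rhos[1] > rhos[2]
        assert rhos[0] > 0.8

    def test_small_intersection_returns_none(self):
        a = make_pairs("A (K)", [0.01], sequences=["AAK"])
        b = make_pairs("B (K)", [0.02], sequences=["BBK"])
        with pytest.warns(UserWarning):
            assert rank_concordance(a, b) is None
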