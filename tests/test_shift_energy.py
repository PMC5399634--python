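"""Bayesian shift energy, calibration and evaluation statistics."""

import math

import numpy as np
import pytest

from csrefine.shift_energy import (
    CalibrationState, ShiftDataset, ShiftEnergyError, amino_acid_offsets,
    apply_offsets, calibrate_per_protein, chi_squared,
    ensemble_average_shieldings, esd_outlier_filter, hybrid_energy,
    ls_slope_offset, marginal_cs_energy, numerical_marginal_oracle,
    predict_shifts, residue_epsilon, shift_statistics,
)
from csrefine.shift_energy import _marginal_type_energy


def _dataset(entries):
    """entries: {atom_type: (sigma, delta)} -> ShiftDataset"""
    data = {}
    for at, (sigma, delta) in entries.items():
        sigma = np.asarray(sigma, float)
        delta = np.asarray(delta, float)
        data[at] = {"sigma": sigma, "delta": delta,
                    "residues": np.arange(1, len(sigma) + 1)}
    return ShiftDataset(data=data)


def _random_regression(rng, n=None):
    n = int(rng.integers(5, 51)) if n is None else n
    sigma = rng.normal(120.0, 4.0, n)
    a, b = rng.normal(-1.0, 0.2), rng.normal(180.0, 5.0)
    s = float(rng.uniform(0.5, 2.0))
    delta = a * sigma + b + rng.normal(0.0, s, n)
    return sigma, delta, a, b, s


class TestLsSlopeOffset:
    def test_identity_data(self):
        sigma = np.linspace(100, 140, 10)
        a, b, rss = ls_slope_offset(sigma, sigma)
        assert (a, b, rss) == pytest.approx((1.0, 0.0, 0.0), abs=1e-10)

    def test_exact_negative_line(self):
        sigma = np.linspace(100, 140, 10)
        a, b, rss = ls_slope_offset(sigma, -sigma + 5.0)
        assert (a, b) == pytest.approx((-1.0, 5.0), abs=1e-10)
        assert rss == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_refinement(self, seed):
        rng = np.random.default_rng(seed)
        sigma, delta, *_ = _random_regression(rng, n=20)

        def rss_of(a, b):
            r = delta - a * sigma - b
            return float(r @ r)

        a_hat, b_hat, rss_hat = ls_slope_offset(sigma, delta)
        # coarse grid around the fit, then local quadratic refinement
        best = min(
            ((rss_of(a, b), a, b)
             for a in np.linspace(a_hat - 0.5, a_hat + 0.5, 41)
             for b in np.linspace(b_hat - 60, b_hat + 60, 41)))
        from scipy.optimize import minimize
        res = minimize(lambda p: rss_of(*p), [best[1], best[2]],
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14})
        assert rss_hat == pytest.approx(res.fun, abs=1e-8)
        assert abs(a_hat - res.x[0]) < 1e-5

    def test_rss_is_true_minimum_under_perturbation(self, rng):
        sigma, delta, *_ = _random_regression(rng, n=25)
        a, b, rss = ls_slope_offset(sigma, delta)
        for _ in range(100):
            da, db = rng.normal(0, 0.05), rng.normal(0, 2.0)
            r = delta - (a + da) * sigma - (b + db)
            assert float(r @ r) >= rss - 1e-10

    def test_constant_sigma_rejected(self):
        with pytest.raises(ShiftEnergyError, match="degenerate"):
            ls_slope_offset(np.full(10, 120.0), np.arange(10.0))


class TestChiSquared:
    def test_identical_and_unit_deviations(self):
        v = np.arange(4.0)
        assert chi_squared(v, v) == 0.0
        assert chi_squared(v, v + 1.0) == pytest.approx(4.0)

    def test_matches_loop_summation(self, rng):
        pred, exp = rng.normal(size=30), rng.normal(size=30)
        assert chi_squared(pred, exp) == pytest.approx(
            sum((e - p) ** 2 for p, e in zip(pred, exp)))

    def test_length_mismatch(self):
        with pytest.raises(ShiftEnergyError):
            chi_squared(np.zeros(3), np.zeros(4))


class TestMarginalEnergy:
    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sigma, delta, _, _, s = _random_regression(rng)
        closed, *_ = _marginal_type_energy(sigma, delta, s)
        oracle = numerical_marginal_oracle(sigma, delta, s)
        assert abs(closed - oracle) / abs(oracle) < 1e-6

    def test_translation_invariance_in_delta_and_sigma(self, rng):
        sigma, delta, *_ = _random_regression(rng, n=15)
        e0, *_ = _marginal_type_energy(sigma, delta, 1.0)
        e1, *_ = _marginal_type_energy(sigma, delta + 7.3, 1.0)
        e2, *_ = _marginal_type_energy(sigma + 11.1, delta, 1.0)
        assert e0 == pytest.approx(e1, abs=1e-8)
        assert e0 == pytest.approx(e2, abs=1e-8)

    def test_sigma_scaling_shifts_energy_by_log_c(self, rng):
        sigma, delta, *_ = _random_regression(rng, n=15)
        e0, *_ = _marginal_type_energy(sigma, delta, 1.0)
        e1, *_ = _marginal_type_energy(3.0 * sigma, delta, 1.0)
        assert e1 - e0 == pytest.approx(math.log(3.0), abs=1e-8)

    def test_doubling_s_on_perfect_fit(self):
        sigma = np.linspace(100, 140, 12)
        delta = 2.0 * sigma + 1.0
        e1, *_ = _marginal_type_energy(sigma, delta, 1.0)
        e2, *_ = _marginal_type_energy(sigma, delta, 2.0)
        assert e2 - e1 == pytest.approx((len(sigma) - 1) * math.log(2.0))

    def test_oracle_unimodal_in_log_s_around_optimal_scale(self):
        rng = np.random.default_rng(0)
        sigma = np.linspace(100, 140, 12)
        delta = 2.0 * sigma + 1.0 + rng.normal(0, 0.3, 12)
        _, _, rss = ls_slope_offset(sigma, delta)
        s_star = math.sqrt(rss / (len(sigma) - 1))
        scales = s_star * np.exp(np.linspace(-1.5, 1.5, 9))
        energies = np.array([numerical_marginal_oracle(sigma, delta, s)
                             for s in scales])
        # energy decreases approaching s_star from both sides: one sign change
        signs = np.sign(np.diff(energies))
        assert signs[0] < 0 < signs[-1]
        assert np.count_nonzero(np.diff(signs)) == 1

    def test_small_types_dropped_with_warning(self, rng):
        sigma, delta, *_ = _random_regression(rng, n=10)
        ds = _dataset({"CA": (sigma, delta), "CB": ([1.0, 2.0], [3.0, 4.0])})
        with pytest.warns(UserWarning, match="CB"):
            out = marginal_cs_energy(ds, {"CA": 1.0, "CB": 1.0})
        assert "CB" in out.dropped and "CA" in out.per_type

    def test_all_types_dropped_is_an_error(self):
        ds = _dataset({"CA": ([1.0, 2.0], [3.0, 4.0])})
        with pytest.warns(UserWarning):
            with pytest.raises(ShiftEnergyError):
                marginal_cs_energy(ds, {"CA": 1.0})

    def test_total_is_sum_of_per_type(self, rng):
        ds = _dataset({
            "CA": _random_regression(rng, n=20)[:2],
            "N": _random_regression(rng, n=15)[:2],
        })
        out = marginal_cs_energy(ds, {"CA": 0.8, "N": 2.8})
        assert out.total == pytest.approx(sum(out.per_type.values()))


class TestHybridEnergy:
    def test_zero_forcefield_returns_cs(self, rng):
        ds = _dataset({"CA": _random_regression(rng, n=20)[:2]})
        e_cs = marginal_cs_energy(ds, {"CA": 1.0}).total
        assert hybrid_energy(0.0, ds, {"CA": 1.0}) == pytest.approx(e_cs)

    def test_empty_dataset_requires_flag(self):
        empty = ShiftDataset(data={})
        with pytest.raises(ShiftEnergyError):
            hybrid_energy(5.0, empty, {})
        assert hybrid_energy(5.0, empty, {}, allow_empty=True) == 5.0


class TestPredictShifts:
    def test_identity_and_arithmetic(self):
        cal = CalibrationState(a={"CA": 1.0, "N": -0.95},
                               b={"CA": 0.0, "N": 180.0},
                               s={"CA": 1.0, "N": 1.0})
        out = predict_shifts(cal, {(1, "CA"): 55.0, (2, "N"): 100.0})
        assert out[(1, "CA")] == pytest.approx(55.0)
        assert out[(2, "N")] == pytest.approx(85.0)

    def test_calibrate_then_predict_consistency(self, rng):
        sigma, delta, *_ = _random_regression(rng, n=25)
        a, b, _ = ls_slope_offset(sigma, delta)
        cal = CalibrationState(a={"CA": a}, b={"CA": b}, s={"CA": 1.0})
        out = predict_shifts(cal, {(i + 1, "CA"): v for i, v in enumerate(sigma)})
        np.testing.assert_allclose(
            [out[(i + 1, "CA")] for i in range(len(sigma))], a * sigma + b)

    def test_missing_type_rejected(self):
        cal = CalibrationState(a={"CA": 1.0}, b={"CA": 0.0}, s={"CA": 1.0})
        with pytest.raises(ShiftEnergyError):
            predict_shifts(cal, {(1, "N"): 100.0})


class TestEsdOutlierFilter:
    def test_near_constant_vector_flags_nothing(self):
        x = np.full(20, 5.0) + 1e-12 * np.arange(20)
        assert not esd_outlier_filter(x).any()

    def test_planted_outlier_found_and_fixed_point(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(100)
        x[17] = 10.0
        mask = esd_outlier_filter(x, alpha=0.05)
        assert list(np.flatnonzero(mask)) == [17]
        assert not esd_outlier_filter(x[~mask], alpha=0.05).any()

    def test_matches_independent_recursive_implementation(self):
        from scipy import stats as ss
        rng = np.random.default_rng(7)
        x = rng.standard_normal(60)
        x[[3, 40]] += np.array([8.0, -9.0])

        def reference_esd(values, alpha, k):
            vals = list(values)
            idx = list(range(len(vals)))
            removed, rs, lams = [], [], []
            for i in range(1, k + 1):
                arr = np.array(vals)
                dev = np.abs(arr - arr.mean())
                j = int(dev.argmax())
                rs.append(dev[j] / arr.std(ddof=1))
                m = len(arr)
                p = 1 - alpha / (2 * m)
                t = ss.t.ppf(p, m - 2)
                lams.append((m - 1) * t / math.sqrt((m - 2 + t * t) * m))
                removed.append(idx[j])
                del vals[j], idx[j]
            keep = 0
            for i in range(len(rs)):
                if rs[i] > lams[i]:
                    keep = i + 1
            return set(removed[:keep])

        mask = esd_outlier_filter(x, alpha=0.05, max_outliers=6)
        assert set(np.flatnonzero(mask)) == reference_esd(x, 0.05, 6)

    def test_short_input_rejected(self):
        with pytest.raises(ShiftEnergyError):
            esd_outlier_filter(np.arange(5.0))


class TestShiftStatistics:
    def test_perfect_prediction(self, random_coil):
        seq = ["ALA"] * 12
        res = np.arange(1, 13)
        exp = np.linspace(50, 60, 12)
        report = shift_statistics({"CA": (res, exp.copy(), exp)}, random_coil, seq)
        assert report.rmsd["CA"] == pytest.approx(0.0, abs=1e-12)
        assert report.pearson_r["CA"] == pytest.approx(1.0)

    def test_rmsd_unchanged_by_random_coil_subtraction(self, random_coil, rng):
        seq = [t for t in ("ALA", "LEU", "SER", "GLY") for _ in range(5)]
        res = np.arange(1, 21)
        exp = rng.normal(57, 3, 20)
        pred = exp + rng.normal(0, 1, 20)
        report = shift_statistics({"CA": (res, pred, exp)}, random_coil, seq)
        rc = np.array([random_coil.lookup(seq, r, "CA") for r in res])
        keep = ~report.outliers["CA"]
        raw = np.sqrt(np.mean((exp - pred)[keep] ** 2))
        secondary = np.sqrt(np.mean(((exp - rc) - (pred - rc))[keep] ** 2))
        assert report.rmsd["CA"] == pytest.approx(raw) == pytest.approx(secondary)

    def test_secondary_r_reported_not_raw(self, random_coil, rng):
        # residue-type means dominate the raw correlation; the secondary
        # (random-coil subtracted) correlation is much lower and is the
        # value the report must carry
        types = ["ALA", "LEU", "SER", "GLY", "VAL"]
        seq, res, exp, pred = [], [], [], []
        for k, t in enumerate(types * 8):
            seq.append(t)
            res.append(k + 1)
            base = random_coil.lookup(seq, k + 1, "CA")
            exp.append(base + rng.normal(0, 1.0))
            pred.append(base + rng.normal(0, 1.0))
        res = np.array(res)
        exp = np.array(exp)
        pred = np.array(pred)
        raw_r = np.corrcoef(pred, exp)[0, 1]
        rc = np.array([random_coil.lookup(seq, r, "CA") for r in res])
        sec_r = np.corrcoef(pred - rc, exp - rc)[0, 1]
        report = shift_statistics({"CA": (res, pred, exp)}, random_coil, seq,
                                  esd_min_points=10 ** 9)
        assert report.pearson_r["CA"] == pytest.approx(sec_r, abs=1e-12)
        assert abs(raw_r) > abs(sec_r)  # the construction worked


class TestResidueEpsilon:
    def test_perfect_prediction_gives_zero(self):
        dev = {i: {"CA": 0.0, "N": 0.0} for i in range(1, 5)}
        eps = residue_epsilon(dev, {"CA": 0.8, "N": 2.8})
        assert all(v == 0.0 for v in eps.values())

    def test_unit_normalized_deviation_anchor(self):
        s = {"CA": 0.8, "CB": 1.5, "N": 2.8}
        dev = {1: {at: s[at] for at in s}}
        assert residue_epsilon(dev, s)[1] == pytest.approx(1.0)

    def test_matches_direct_recomputation(self, rng):
        s = {"CA": 0.8, "H": 0.39}
        dev = {i: {"CA": rng.normal(), "H": rng.normal()} for i in range(1, 8)}
        eps = residue_epsilon(dev, s)
        for i, d in dev.items():
            manual = math.sqrt(np.mean([(d[at] / s[at]) ** 2 for at in d]))
            assert eps[i] == pytest.approx(manual)

    def test_residue_without_shifts_excluded(self):
        eps = residue_epsilon({1: {"CA": 1.0}, 2: {}}, {"CA": 1.0})
        assert 2 not in eps


class TestAminoAcidOffsets:
    def test_single_observation(self):
        offsets = amino_acid_offsets([[("ALA", "CA", 52.0, 52.7)]])
        assert offsets[("ALA", "CA")] == pytest.approx(0.7)
        corrected = apply_offsets([("ALA", "CA", 52.0, 52.7)], offsets)
        assert corrected[0][3] - corrected[0][2] == pytest.approx(0.0)

    def test_symmetric_deviations_cancel(self):
        pairs = [("LEU", "CA", 55.0, 55.0 + d) for d in (-0.4, 0.4, -1.1, 1.1)]
        assert amino_acid_offsets([pairs])[("LEU", "CA")] == pytest.approx(0.0)

    def test_mean_of_per_protein_means_not_pooled(self):
        # protein 1: one observation with deviation 0.4
        # protein 2: three observations with deviation 0.8
        p1 = [("ALA", "CA", 50.0, 50.4)]
        p2 = [("ALA", "CA", 50.0, 50.8)] * 3
        offsets = amino_acid_offsets([p1, p2])
        assert offsets[("ALA", "CA")] == pytest.approx(0.6)  # not 0.7 (pooled)


class TestEnsembleAveraging:
    def test_identical_maps(self):
        m = {(1, "CA"): 120.0, (2, "CA"): 121.0}
        assert ensemble_average_shieldings([m, dict(m)]) == m

    def test_two_member_mean(self):
        out = ensemble_average_shieldings([{(1, "CA"): 10.0}, {(1, "CA"): 20.0}])
        assert out[(1, "CA")] == pytest.approx(15.0)

    def test_key_mismatch_rejected(self):
        with pytest.raises(ShiftEnergyError):
            ensemble_average_shieldings([{(1, "CA"): 1.0}, {(2, "CA"): 1.0}])

    def test_averaging_reduces_calibrated_rmsd_on_noisy_ensembles(self):
        # noisy per-member shieldings around a clean linear relation:
        # averaging must help on average over seeds
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            true_sigma = rng.normal(120, 4, 25)
            delta = -1.0 * true_sigma + 180.0 + rng.normal(0, 0.3, 25)
            pairs = [(i + 1, "CA", delta[i]) for i in range(25)]
            members = []
            for _ in range(8):
                noisy = true_sigma + rng.normal(0, 1.0, 25)
                members.append({(i + 1, "CA"): noisy[i] for i in range(25)})
            avg = ensemble_average_shieldings(members)
            _, _, rmsd_avg = calibrate_per_protein(avg, pairs)
            member_rmsds = [calibrate_per_protein(m, pairs)[2] for m in members]
            if rmsd_avg <= np.mean(member_rmsds):
                wins += 1
        assert wins >= 45


class TestParameterRecovery:
    def test_slope_offset_and_scale_recovered(self):
        """Aggregate recovery of (a, b, s) from simulated calibrations."""
        a_err, b_err, s_ratio = [], [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sigma = rng.normal(120, 4, 200)
            delta = -1.0 * sigma + 180.0 + rng.normal(0, 1.0, 200)
            a_hat, b_hat, rss = ls_slope_offset(sigma, delta)
            a_err.append(a_hat - (-1.0))
            b_err.append(b_hat - 180.0)
            # profile optimum of the marginalized energy over s
            s_star = math.sqrt(rss / (len(sigma) - 1))
            scales = np.exp(np.linspace(math.log(0.2), math.log(5.0), 400))
            energies = [_marginal_type_energy(sigma, delta, s)[0] for s in scales]
            s_min = scales[int(np.argmin(energies))]
            assert s_min == pytest.approx(s_star, rel=0.02)
            s_ratio.append(s_min / 1.0)
        assert abs(np.mean(a_err)) < 0.03
        assert abs(np.mean(b_err)) < 3.0
        assert abs(np.mean(s_ratio) - 1.0) < 0.15
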