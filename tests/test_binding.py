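"""Sequential binding model: fractions, mass balance, and fitting."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidtherm import binding
from lipidtherm.binding import (
    TitrationSeries,
    fit_binding_constants,
    ka_from_kd,
    kd_from_ka,
    predict_mole_fractions,
    pseudo_chi2,
    read_titration_csv,
    solve_free_ligand,
    species_fractions,
)
from lipidtherm.simulate import (
    EventThermo,
    GroundTruth,
    NoiseModel,
    generate_titration_series,
)



def brute_force_fractions(ka, l_free):
    """Direct evaluation of the binding polynomial, term by term."""
    weights = []
    for n in range(len(ka) + 1):
        w = l_free**n
        for j in range(n):
            w *= ka[j]
        weights.append(w)
    total = sum(weights)
    return np.array([w / total for w in weights])


def brute_force_free_ligand(ka, p_total, l_total, n_grid=4000):
    """Grid + sign-change bracketing, refined by bisection."""
    def residual(l):
        f = brute_force_fractions(ka, l)
        return l + p_total * sum(i * fi for i, fi in enumerate(f)) - l_total

    grid = np.linspace(0.0, l_total, n_grid)
    vals = np.array([residual(l) for l in grid])
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    lo, hi = (grid[idx[0]], grid[idx[0] + 1]) if len(idx) else (0.0, l_total)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestSpeciesFractions:
    def test_no_ligand_is_all_apo(self, wt_ka):
        assert species_fractions(wt_ka, 0.0) == pytest.approx([1, 0, 0, 0])

    def test_half_saturation_single_site(self):
        kd = 2.5
        assert species_fractions([1 / kd], kd) == pytest.approx([0.5, 0.5])

    def test_wild_type_at_kd1_matches_polynomial(self, wt_ka):
        expected = brute_force_fractions(list(wt_ka), 0.68)
        result = species_fractions(wt_ka, 0.68)
        np.testing.assert_allclose(result, expected, rtol=1e-12)
        # frozen from the brute-force polynomial evaluation
        np.testing.assert_allclose(result, [0.435, 0.435, 0.117, 0.013], atol=5e-4)

    @given(
        kds=st.lists(st.floats(0.1, 50.0), min_size=1, max_size=3),
        l_free=st.floats(0.0, 20.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_normalisation_and_stepwise_ratio(self, kds, l_free):
        ka = 1.0 / np.asarray(kds)
        f = species_fractions(ka, l_free)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        for n in range(1, len(f)):
            assert f[n] == pytest.approx(ka[n - 1] * l_free * f[n - 1], rel=1e-9, abs=1e-15)

    @pytest.mark.parametrize("ka,l_free", [([1.0], -0.1), ([0.0], 1.0), ([-2.0], 1.0)])
    def test_domain_errors(self, ka, l_free):
        with pytest.raises(ValueError):
            species_fractions(ka, l_free)


class TestFreeLigand:
    def test_zero_ligand(self, wt_ka):
        assert solve_free_ligand(wt_ka, 0.39, 0.0) == 0.0

    def test_no_protein(self, wt_ka):
        assert solve_free_ligand(wt_ka, 0.0, 5.0) == 5.0

    def test_wild_type_study_conditions(self, wt_ka):
        # 0.39 uM protein, 0.6 uM lipid: frozen from the bisection oracle
        l_free = solve_free_ligand(wt_ka, 0.39, 0.6)
        assert l_free == pytest.approx(0.41224, abs=1e-4)
        oracle = brute_force_free_ligand(list(wt_ka), 0.39, 0.6)
        assert l_free == pytest.approx(oracle, abs=1e-9)

    @given(
        kds=st.lists(st.floats(0.1, 50.0), min_size=1, max_size=3),
        p_total=st.floats(0.1, 1.0),
        l_total=st.floats(0.0, 20.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mass_balance(self, kds, p_total, l_total):
        ka = 1.0 / np.asarray(kds)
        l_free = solve_free_ligand(ka, p_total, l_total)
        assert 0.0 <= l_free <= l_total
        f = species_fractions(ka, l_free)
        bound = p_total * np.arange(len(f)) @ f
        assert abs(l_free + bound - l_total) <= 1e-10 * max(l_total, 1e-12)

    def test_matches_grid_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            kd = rng.uniform(0.1, 50.0, size=rng.integers(1, 4))
            p_total = rng.uniform(0.1, 1.0)
            l_total = rng.uniform(0.0, 20.0)
            ka = 1.0 / kd
            got = solve_free_ligand(ka, p_total, l_total)
            want = brute_force_free_ligand(list(ka), p_total, l_total)
            assert got == pytest.approx(want, abs=1e-6)


class TestPredictions:
    def test_zero_point_row(self, wt_ka):
        rows = predict_mole_fractions(wt_ka, 0.39, [0.0])
        np.testing.assert_allclose(rows[0], [1, 0, 0, 0])

    def test_apo_fraction_strictly_decreasing(self, wt_ka):
        grid = np.linspace(0.0, 10.0, 60)
        rows = predict_mole_fractions(wt_ka, 0.39, grid)
        np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(rows[:, 0]) < 0)
        occupancy = rows @ np.arange(rows.shape[1])
        assert np.all(np.diff(occupancy) > 0)

    def test_round_trip_with_generator(self, wt_truth, noiseless):
        panel = generate_titration_series(wt_truth, "WT", 298.0, noiseless)
        wide = panel.pivot_table(
            index="ligand_total_uM", columns="n_bound", values="mole_fraction"
        ).sort_index()
        from lipidtherm.simulate import ka_from_thermo

        ka = [ka_from_thermo(wt_truth, "WT", n, 298.0) for n in (1, 2, 3)]
        pred = predict_mole_fractions(ka, 0.39, wide.index.to_numpy())
        np.testing.assert_allclose(wide.to_numpy(), pred, atol=1e-10)


class TestPseudoChi2:
    def test_identical_is_zero(self):
        a = np.random.default_rng(0).random((3, 4))
        assert pseudo_chi2(a, a) == 0.0

    def test_single_deviation(self):
        a = np.zeros((2, 3))
        b = a.copy()
        b[1, 2] = 0.1
        assert pseudo_chi2(a, b) == pytest.approx(0.01)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((3, 4)), rng.random((3, 4))
        acc = 0.0
        for j in range(3):
            for k in range(4):
                acc += (a[j, k] - b[j, k]) ** 2
        assert pseudo_chi2(a, b) == pytest.approx(acc, rel=1e-14)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pseudo_chi2(np.zeros((2, 2)), np.zeros((3, 2)))


class TestFit:
    def test_noiseless_recovery_is_exact(self):
        kd_true = np.array([0.7, 2.5])
        ka = 1.0 / kd_true
        grid = np.array([0.0, 0.3, 0.7, 1.2, 2.0, 3.5, 6.0, 10.0])
        series = TitrationSeries(
            variant="syn",
            temperature=298.0,
            protein_total=0.39,
            ligand_total=grid,
            fractions=predict_mole_fractions(ka, 0.39, grid),
        )
        fit = fit_binding_constants(series, 2)
        assert fit.converged
        np.testing.assert_allclose(fit.constants.kd, kd_true, rtol=1e-6)
        assert fit.pseudo_chi2 < 1e-16
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_replicates_recover_kd1_within_ten_percent(self, wt_truth):
        noise = NoiseModel(fraction_noise_sd=0.01, n_replicates=3, seed=5)
        panel = generate_titration_series(wt_truth, "WT", 298.0, noise)
        buf = io.StringIO()
        panel.to_csv(buf, index=False)
        buf.seek(0)
        fits = [fit_binding_constants(s) for s in read_titration_csv(buf)]
        kd1 = np.mean([f.constants.kd[0] for f in fits])
        assert kd1 == pytest.approx(0.676, rel=0.10)
        # poorest replicate keeps the fit quality reported for real data
        assert min(f.r_squared for f in fits) >= 0.94

    def test_low_noise_fits_are_nearly_unbiased(self):
        truth = GroundTruth(
            t0=298.0, variants={"v": [EventThermo(dg_t0=-35.2, dh_t0=45.0)]}
        )
        kd_true = 1e6 * np.exp(-35.2 / (8.314462618e-3 * 298.0))
        noise = NoiseModel(fraction_noise_sd=0.01, n_replicates=1, seed=0)
        rng = np.random.default_rng(2024)
        estimates = []
        for _ in range(200):
            panel = generate_titration_series(truth, "v", 298.0, noise, rng=rng)
            buf = io.StringIO()
            panel.to_csv(buf, index=False)
            buf.seek(0)
            (series,) = read_titration_csv(buf)
            fit = fit_binding_constants(series, 1, multistart=False)
            estimates.append(fit.constants.kd[0])
        bias = abs(np.mean(estimates) - kd_true) / kd_true
        assert bias < 0.03

    def test_refuses_uninformative_titration(self, wt_ka):
        series = TitrationSeries(
            variant="x",
            temperature=298.0,
            protein_total=0.39,
            ligand_total=np.array([0.0]),
            fractions=np.array([[1.0, 0.0, 0.0, 0.0]]),
        )
        with pytest.raises(ValueError, match="titration points"):
            fit_binding_constants(series, 3)


class TestConstants:
    def test_reciprocal_and_involution(self):
        kd = np.array([0.68, 2.53, 6.01])
        ka = ka_from_kd(kd)
        np.testing.assert_allclose(1.0 / ka, kd)
        np.testing.assert_allclose(ka_from_kd(1.0 / ka_from_kd(kd)), ka_from_kd(kd))

    def test_wild_type_association_constants(self):
        # replicate-mean stepwise K_A for the 298 K wild type
        constants = binding.BindingConstants(ka=[1.4706, 0.3953, 0.1664], temperature=298.0)
        np.testing.assert_allclose(kd_from_ka(constants), [0.68, 2.53, 6.01], atol=0.005)


class TestCsvIO:
    def test_renormalises_and_orders(self, wt_truth, noiseless):
        panel = generate_titration_series(wt_truth, "WT", 298.0, noiseless)
        panel["mole_fraction"] *= 7.3  # arbitrary common scale
        buf = io.StringIO()
        panel.to_csv(buf, index=False)
        buf.seek(0)
        (series,) = read_titration_csv(buf)
        np.testing.assert_allclose(series.fractions.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(series.ligand_total) > 0)

    def test_intensity_mode(self, wt_truth, noiseless):
        panel = generate_titration_series(wt_truth, "WT", 298.0, noiseless)
        panel = panel.rename(columns={"mole_fraction": "intensity"})
        panel["intensity"] *= 1e5
        buf = io.StringIO()
        panel.to_csv(buf, index=False)
        buf.seek(0)
        (series,) = read_titration_csv(buf, intensity=True)
        np.testing.assert_allclose(series.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="missing columns"):
            read_titration_csv(io.StringIO("variant,temperature_K\nWT,298\n"))
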