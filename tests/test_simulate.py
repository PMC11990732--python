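"""Mass-action equilibrium solvers and the synthetic titration generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quenchbind import (
    SimConfig,
    competitive_species,
    double_log_fit,
    extract_quench_curve,
    simulate_multi_temperature,
    simulate_titration,
    solve_equilibrium_1to1,
    solve_equilibrium_competitive,
    stern_volmer_fit,
    vant_hoff_fit,
)

from conftest import DELTA_H, DELTA_S, PROTEIN_CONC


def bisect_1to1(P, Q, Ka, iters=120):
    """Independent oracle: bisection on the equilibrium residual."""
    if Ka == 0 or P == 0 or Q == 0:
        return 0.0

    def residual(x):  # Ka (P-x)(Q-x) - x, decreasing in x on [0, min(P,Q)]
        return Ka * (P - x) * (Q - x) - x

    lo, hi = 0.0, min(P, Q)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def grid_search_competitive(P, Q, M, KaQ, KaM, n_grid=10_000, iters=80):
    """Independent oracle: log-grid bracket + bisection on free protein."""

    def residual(p):
        return p * (1 + KaQ * Q / (1 + KaQ * p) + KaM * M / (1 + KaM * p)) - P

    grid = np.concatenate([[0.0], np.geomspace(P * 1e-12, P, n_grid)])
    vals = np.array([residual(p) for p in grid])
    idx = int(np.searchsorted(vals > 0, True))  # residual increasing in p
    lo, hi = grid[max(idx - 1, 0)], grid[min(idx, len(grid) - 1)]
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if residual(mid) <= 0:
            lo = mid
        else:
            hi = mid
    p = 0.5 * (lo + hi)
    return KaQ * p * Q / (1 + KaQ * p), KaM * p * M / (1 + KaM * p)


class TestOneToOneSolver:
    def test_zero_affinity_gives_no_complex(self):
        assert solve_equilibrium_1to1(1e-6, 1e-6, 0.0) == 0.0

    def test_known_quadratic_root(self):
        # P = Q = 1e-6, Ka = 1e6: x = (3 - sqrt(5))/2 * 1e-6
        x = solve_equilibrium_1to1(1e-6, 1e-6, 1e6)
        assert x == pytest.approx((3 - np.sqrt(5)) / 2 * 1e-6, rel=1e-12)

    def test_stoichiometric_limit_at_huge_affinity(self):
        x = solve_equilibrium_1to1(1.6e-6, 1.0e-6, 1e15)
        assert x == pytest.approx(1.0e-6, rel=1e-9)

    @given(
        P=st.floats(min_value=1e-9, max_value=1e-3),
        Q=st.floats(min_value=1e-9, max_value=1e-3),
        logKa=st.floats(min_value=0.0, max_value=12.0),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_bisection_oracle_and_conserves_mass(self, P, Q, logKa):
        Ka = 10.0**logKa
        x = solve_equilibrium_1to1(P, Q, Ka)
        ref = bisect_1to1(P, Q, Ka)
        assert x == pytest.approx(ref, rel=1e-10, abs=1e-25)
        # species computed from the root satisfy both mass balances exactly
        assert (P - x) + x == pytest.approx(P, rel=1e-12)
        assert (Q - x) + x == pytest.approx(Q, rel=1e-12)
        assert 0.0 <= x <= min(P, Q)

    def test_monotone_in_affinity_and_totals(self):
        kas = np.geomspace(1e3, 1e9, 25)
        xs = [solve_equilibrium_1to1(1.6e-6, 2e-6, ka) for ka in kas]
        assert np.all(np.diff(xs) >= 0)
        qs = np.linspace(0, 5e-6, 25)
        xq = [solve_equilibrium_1to1(1.6e-6, q, 1e6) for q in qs]
        assert np.all(np.diff(xq) >= 0)


class TestCompetitiveSolver:
    def test_reduces_to_1to1_without_marker(self):
        pq, pm = solve_equilibrium_competitive(1.6e-6, 2e-6, 0.0, 3.98e6, 5e6)
        assert pm == 0.0
        assert pq == pytest.approx(solve_equilibrium_1to1(1.6e-6, 2e-6, 3.98e6), rel=1e-12)

    def test_symmetric_ligands_bind_equally(self):
        pq, pm = solve_equilibrium_competitive(1.6e-6, 2e-6, 2e-6, 1e6, 1e6)
        assert pq == pytest.approx(pm, rel=1e-10)

    @given(
        P=st.floats(min_value=1e-8, max_value=1e-4),
        Q=st.floats(min_value=1e-8, max_value=1e-4),
        M=st.floats(min_value=1e-8, max_value=1e-4),
        logKaQ=st.floats(min_value=2.0, max_value=9.0),
        logKaM=st.floats(min_value=2.0, max_value=9.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_grid_oracle_and_conserves_mass(self, P, Q, M, logKaQ, logKaM):
        KaQ, KaM = 10.0**logKaQ, 10.0**logKaM
        sp = competitive_species(P, Q, M, KaQ, KaM)
        ref_pq, ref_pm = grid_search_competitive(P, Q, M, KaQ, KaM)
        assert sp["PQ"] == pytest.approx(ref_pq, rel=1e-6, abs=1e-20)
        assert sp["PM"] == pytest.approx(ref_pm, rel=1e-6, abs=1e-20)
        assert sp["P_free"] + sp["PQ"] + sp["PM"] == pytest.approx(P, rel=1e-12)
        assert sp["Q_free"] + sp["PQ"] == pytest.approx(Q, rel=1e-12)
        assert sp["M_free"] + sp["PM"] == pytest.approx(M, rel=1e-12)


class TestSimulator:
    def test_seeded_runs_are_bit_identical(self):
        cfg = SimConfig(noise_sigma_frac=0.02, seed=7)
        a, _ = simulate_titration(cfg)
        b, _ = simulate_titration(cfg)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.intensities, sb.intensities)

    def test_different_seeds_differ(self):
        a, _ = simulate_titration(SimConfig(noise_sigma_frac=0.02, seed=1))
        b, _ = simulate_titration(SimConfig(noise_sigma_frac=0.02, seed=2))
        assert not np.array_equal(a.spectra[1].intensities, b.spectra[1].intensities)

    def test_static_generation_closes_the_loop_with_binding_fit(self):
        series, truth = simulate_titration(SimConfig(Ka_true=2.5e6, seed=0))
        res = double_log_fit(extract_quench_curve(series), PROTEIN_CONC)
        assert res.K_a == pytest.approx(2.5e6, rel=1e-3)

    def test_dynamic_generation_closes_the_loop_with_sv_fit(self, dynamic_series):
        series, truth = dynamic_series
        res = stern_volmer_fit(extract_quench_curve(series))
        assert res.K_SV == pytest.approx(truth["config"]["Ksv_true"], rel=1e-10)

    def test_multi_temperature_recovers_thermo_pair(self):
        cfg = SimConfig(
            temperatures=(298.0, 303.0, 308.0), delta_H=DELTA_H, delta_S=DELTA_S
        )
        ka_fit = {}
        for T, (series, truth) in simulate_multi_temperature(cfg).items():
            res = double_log_fit(extract_quench_curve(series), PROTEIN_CONC)
            ka_fit[T] = res.K_a
        thermo = vant_hoff_fit(ka_fit)
        assert thermo.delta_H == pytest.approx(DELTA_H, rel=0.01)
        assert thermo.delta_S == pytest.approx(DELTA_S, rel=0.01)

    def test_truth_record_names_the_generator(self):
        _, truth = simulate_titration(SimConfig(seed=5))
        assert "PCG64" in truth["rng"]
        assert truth["config"]["seed"] == 5

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(mechanism="bogus"), "mechanism"),
            (dict(mechanism="static_competitive"), "marker_Ka"),
            (dict(quencher_concs=(1e-6, 2e-6)), "include 0"),
            (dict(band_sigma=0.0), "band_sigma"),
            (dict(complex_brightness=1.0), "complex_brightness"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SimConfig(**kwargs)
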