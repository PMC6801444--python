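"""Umbrella reweighting (WHAM/MBAR), PMF surfaces, minimax barrier."""

import numpy as np
import pytest

import chiralmem as cm
from chiralmem import pmf as pm
from chiralmem import synthetic as syn

A_HARM = 8.0  # kBT/nm^2, analytic test surface curvature
M_HARM = 1.75  # nm, its minimum


def analytic_harmonic_windows(n_per_window=8000, seed=0, k_bias=1000.0,
                              centers=None):
    """Windows sampled *exactly* from the biased density of the analytic
    1D harmonic free-energy surface U(dz) = A_HARM (dz - M_HARM)^2."""
    rng = np.random.default_rng(seed)
    centers = np.linspace(1.0, 2.5, 16) if centers is None else centers
    kT = pm.KB_KJ_PER_MOL_K * pm.DEFAULT_TEMPERATURE
    b = 0.5 * k_bias / kT  # bias curvature in kBT/nm^2
    windows = []
    for c in centers:
        prec = A_HARM + b
        mu = (A_HARM * M_HARM + b * c) / prec
        dz = rng.normal(mu, np.sqrt(0.5 / prec), size=n_per_window)
        theta = rng.uniform(0.0, 360.0, size=n_per_window)
        windows.append(pm.UmbrellaWindow(center=float(c), k_bias=k_bias, dz=dz,
                                         theta=theta,
                                         observables={"one": np.ones_like(dz),
                                                      "dz": dz.copy()}))
    return pm.UmbrellaWindowSet(windows=windows)


def pmf_rms_error(surface):
    """RMS deviation of the estimated 1D profile from the analytic surface."""
    dz = surface.dz_centers
    ref = A_HARM * (dz - M_HARM) ** 2
    est = surface.pmf_dz
    sel = np.isfinite(est) & (ref < 6.0)
    shift = np.mean(est[sel] - ref[sel])
    return float(np.sqrt(np.mean((est[sel] - ref[sel] - shift) ** 2)))


def surface_from_analytic(ref_surface, n_dz=60, n_theta=72):
    """Bin an analytic surface directly into a PmfSurface (no sampling)."""
    grid = pm.GridSpec(n_dz=n_dz, n_theta=n_theta)
    dz_c = 0.5 * (grid.dz_edges[:-1] + grid.dz_edges[1:])
    th_c = 0.5 * (grid.theta_edges[:-1] + grid.theta_edges[1:])
    F = ref_surface.energy(dz_c[:, None], th_c[None, :])
    F = F - F.min()
    return pm.PmfSurface(dz_edges=grid.dz_edges, theta_edges=grid.theta_edges,
                         free_energy=F, mask=np.ones_like(F, dtype=bool),
                         estimator="analytic", f_windows=np.zeros(1))


class TestWindowSet:
    def test_index_convention_matches_center_ladder(self):
        ws = analytic_harmonic_windows(n_per_window=10)
        assert ws.window(16).center == pytest.approx(2.5)
        assert ws.window(8).center == pytest.approx(1.7)
        assert ws.window(1).center == pytest.approx(1.0)

    def test_non_finite_samples_rejected(self):
        with pytest.raises(ValueError):
            pm.UmbrellaWindow(center=1.5, k_bias=1000.0,
                              dz=np.array([1.5, np.nan]))


class TestEstimators:
    def test_mbar_recovers_analytic_harmonic_surface(self):
        ws = analytic_harmonic_windows(seed=1)
        surf = pm.estimate_pmf(ws, estimator="mbar", discard_fraction=0.0,
                               subsample=False)
        assert pmf_rms_error(surf) < 0.1

    def test_wham_recovers_analytic_harmonic_surface(self):
        ws = analytic_harmonic_windows(seed=2)
        surf = pm.estimate_pmf(ws, estimator="wham", discard_fraction=0.0,
                               subsample=False)
        assert pmf_rms_error(surf) < 0.1

    def test_wham_and_mbar_agree_binwise(self, barrier_windows):
        a = pm.estimate_pmf(barrier_windows, estimator="mbar")
        b = pm.estimate_pmf(barrier_windows, estimator="wham")
        sel = a.mask & b.mask & (a.free_energy < 8.0) & (b.free_energy < 8.0)
        assert np.nanmax(np.abs(a.free_energy[sel] - b.free_energy[sel])) < 0.2

    def test_gauge_invariance_under_constant_bias_offset(self):
        ws = analytic_harmonic_windows(seed=3, n_per_window=3000)
        base = pm.estimate_pmf(ws, estimator="mbar", discard_fraction=0.0,
                               subsample=False)
        for w in ws.windows:
            w.bias_offset = 3.7  # kJ/mol, same for every window
        shifted = pm.estimate_pmf(ws, estimator="mbar", discard_fraction=0.0,
                                  subsample=False)
        np.testing.assert_allclose(shifted.free_energy[base.mask],
                                   base.free_energy[base.mask], atol=1e-8)

    def test_error_shrinks_as_samples_grow(self):
        err_small = pmf_rms_error(pm.estimate_pmf(
            analytic_harmonic_windows(n_per_window=2000, seed=4),
            estimator="mbar", discard_fraction=0.0, subsample=False))
        err_large = pmf_rms_error(pm.estimate_pmf(
            analytic_harmonic_windows(n_per_window=8000, seed=4),
            estimator="mbar", discard_fraction=0.0, subsample=False))
        assert err_large < 0.75 * err_small

    def test_single_window_flat_surface_gives_flat_pmf(self):
        surf_ref = cm.ReferenceSurface.flat()
        ws = cm.sample_umbrella(surf_ref, centers=[1.75], k_bias=200.0,
                                n_samples=30000, seed=5, check_overlap=False)
        surf = pm.estimate_pmf(ws, grid=pm.GridSpec(dz_min=1.65, dz_max=1.85,
                                                    n_dz=5, n_theta=6))
        vals = surf.free_energy[surf.mask]
        assert vals.max() - vals.min() < 0.5

    def test_disjoint_windows_raise_overlap_error(self):
        rng = np.random.default_rng(6)
        mk = lambda c: pm.UmbrellaWindow(center=c, k_bias=1000.0,
                                         dz=rng.normal(c, 0.01, 500),
                                         theta=rng.uniform(0, 360, 500))
        ws = pm.UmbrellaWindowSet(windows=[mk(1.2), mk(2.4)])
        with pytest.raises(pm.OverlapError):
            pm.reweight(ws, discard_fraction=0.0, subsample=False)

    def test_surface_normalization_and_masking(self, barrier_windows):
        surf = pm.estimate_pmf(barrier_windows)
        assert np.nanmin(surf.free_energy) == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.isnan(surf.free_energy[~surf.mask]))


class TestReweightedExpectation:
    def test_constant_observable_normalizes_to_one(self):
        ws = analytic_harmonic_windows(seed=7, n_per_window=2000)
        out = pm.reweighted_expectation(ws, "one", discard_fraction=0.0,
                                        subsample=False)
        np.testing.assert_allclose(out["mean"][out["mask"]], 1.0, atol=1e-12)
        np.testing.assert_allclose(out["std"][out["mask"]], 0.0, atol=1e-12)

    def test_dz_expectation_lies_within_bin_bounds(self):
        ws = analytic_harmonic_windows(seed=8, n_per_window=2000)
        edges = pm.GridSpec().dz_edges
        out = pm.reweighted_expectation(ws, "dz", dz_edges=edges,
                                        discard_fraction=0.0, subsample=False)
        for b in np.flatnonzero(out["mask"]):
            assert edges[b] <= out["mean"][b] <= edges[b + 1]

    def test_matches_direct_unbiased_simulation(self):
        # theta-dz coupled well: E[cos(theta) | dz] varies along dz
        surf = cm.ReferenceSurface(
            basins=[syn.GaussianBasin(1.75, 200.0, 2.5, 0.3, 60.0)],
            walls=(1.3, 2.2), temperature=pm.DEFAULT_TEMPERATURE)
        obs = {"cos_t": lambda dz, th: np.cos(np.radians(th))}
        ws = cm.sample_umbrella(surf, centers=np.linspace(1.4, 2.1, 8),
                                k_bias=500.0, n_samples=6000, seed=9,
                                observables=obs)
        edges = np.linspace(1.4, 2.1, 8)
        rew = pm.reweighted_expectation(ws, "cos_t", dz_edges=edges)
        cfg = syn.LangevinConfig(total_time=400.0, seed=10, init_dz=1.75)
        traces = cm.simulate_traces(surf, cfg, 20)
        dz = np.concatenate([t.dz[2000:] for t in traces])
        th = np.concatenate([t.theta[2000:] for t in traces])
        direct = np.full(edges.size - 1, np.nan)
        idx = np.digitize(dz, edges) - 1
        for b in range(edges.size - 1):
            sel = idx == b
            if sel.sum() > 500:
                direct[b] = np.cos(np.radians(th[sel])).mean()
        both = rew["mask"] & np.isfinite(direct)
        assert both.sum() >= 4
        np.testing.assert_allclose(rew["mean"][both], direct[both], atol=0.1)

    def test_unknown_observable_rejected(self):
        ws = analytic_harmonic_windows(seed=11, n_per_window=200)
        with pytest.raises(KeyError):
            pm.reweighted_expectation(ws, "absent", discard_fraction=0.0,
                                      subsample=False)


class TestBarrier:
    def test_analytic_double_basin_barrier_recovered(self, barrier_surface):
        surf = surface_from_analytic(barrier_surface)
        rep = pm.find_barrier(surf, seed_pre=(2.2, 90.0), seed_post=(1.2, 230.0))
        assert rep.barrier == pytest.approx(barrier_surface.saddle_info["barrier"],
                                            abs=0.3)
        assert rep.saddle[0] == pytest.approx(1.8, abs=0.05)
        assert rep.f_saddle == max(f for f in
                                   (surf.free_energy[surf.bin_index(*p)]
                                    for p in rep.path))

    def test_downhill_funnel_has_negligible_barrier(self, downhill_surface):
        surf = surface_from_analytic(downhill_surface)
        rep = pm.find_barrier(surf, seed_pre=(2.2, 230.0), seed_post=(1.2, 230.0))
        assert rep.barrier < 0.3

    def test_minimax_level_direction_invariant(self, barrier_surface):
        surf = surface_from_analytic(barrier_surface)
        fwd = pm.find_barrier(surf, seed_pre=(2.2, 90.0), seed_post=(1.2, 230.0))
        rev = pm.find_barrier(surf, seed_pre=(1.2, 230.0), seed_post=(2.2, 90.0))
        assert fwd.f_saddle == pytest.approx(rev.f_saddle, abs=1e-12)

    def test_unsampled_seed_bin_rejected(self, barrier_windows):
        surf = pm.estimate_pmf(barrier_windows)
        surf.mask[surf.bin_index(2.2, 90.0)] = False
        surf.free_energy[surf.bin_index(2.2, 90.0)] = np.nan
        with pytest.raises(pm.BarrierError):
            pm.find_barrier(surf, seed_pre=(2.2, 90.0), seed_post=(1.2, 230.0))

    def test_statistical_inefficiency_of_correlated_series(self):
        rng = np.random.default_rng(12)
        # AR(1) with phi=0.9 has g = (1+phi)/(1-phi) = 19
        x = np.empty(20000)
        x[0] = 0.0
        for i in range(1, x.size):
            x[i] = 0.9 * x[i - 1] + rng.standard_normal()
        g = pm.statistical_inefficiency(x)
        assert g == pytest.approx(19.0, rel=0.3)
        assert pm.statistical_inefficiency(rng.standard_normal(5000)) < 1.5
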