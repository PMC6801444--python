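"""Generators: peptide/bilayer construction, surfaces, Langevin, fixtures."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import chiralmem as cm
from chiralmem import kinetics as kin
from chiralmem import synthetic as syn
from chiralmem.contacts import ContactPolicy, trp_head_contacts


class TestPeptide:
    def test_c6_composition_and_fragments(self, peptide_L):
        assert len(peptide_L.sequence) == 18
        assert peptide_L.trp_index == 10
        assert peptide_L.polarity_class[1] == syn.POLAR_CHARGED
        assert peptide_L.polarity_class[10] == syn.NONPOLAR
        frags = {}
        for r, f in peptide_L.fragment_assignment.items():
            frags.setdefault(f, []).append(r)
        assert len(frags) == 4
        trp_frag = peptide_L.fragment_assignment[10]
        longest = max(len(v) for v in frags.values())
        assert len(frags[trp_frag]) == longest == 4

    def test_enantiomers_are_exact_mirror_images(self, peptide_L, peptide_D):
        # mirroring is an isometry: all intra-peptide distances match
        assert np.abs(pdist(peptide_L.coords) - pdist(peptide_D.coords)).max() < 1e-9
        assert peptide_D.chirality == "D"
        np.testing.assert_allclose(peptide_D.coords[:, [0, 2]],
                                   peptide_L.coords[:, [0, 2]], atol=1e-12)

    def test_ideal_helix_rise_and_twist(self, peptide_L):
        ca = peptide_L.ca_coords()
        rises = np.diff(ca[:, 0])
        np.testing.assert_allclose(rises, syn.HELIX_RISE, atol=1e-12)
        # wheel angle advances 100 deg per residue about the +x axis
        ang = np.degrees(np.arctan2(-ca[:, 1], ca[:, 2]))
        steps = np.diff(ang) % 360.0
        np.testing.assert_allclose(steps, syn.HELIX_TWIST, atol=1e-9)

    def test_unknown_residue_rejected(self):
        with pytest.raises(syn.UnknownResidueError):
            cm.build_peptide("RLXA")
        with pytest.raises(syn.UnknownResidueError):
            cm.build_peptide("")

    def test_all_polar_sequence_has_no_fragments_or_trp(self):
        pep = cm.build_peptide("RRR")
        assert len(pep.sequence) == 3
        assert pep.trp_index is None
        assert pep.fragment_assignment == {}


class TestBilayer:
    def test_leaflets_box_and_layering(self):
        bl = cm.build_bilayer(128, 0.68, seed=1)
        assert len(bl.lipids) == 128
        assert sum(1 for l in bl.lipids if l.leaflet == "upper") == 64
        assert bl.box[0] == pytest.approx(np.sqrt(64 * 0.68), rel=1e-12)
        for lipid in bl.lipids:
            head_z = np.abs(np.atleast_2d(lipid.head_atoms)[:, 2])
            tail_z = np.abs(np.atleast_2d(lipid.tail_atoms)[:, 2])
            c2_z = abs(lipid.c2_atom[2])
            assert head_z.min() > c2_z > tail_z.max()

    def test_minimal_system_and_odd_count(self):
        bl = cm.build_bilayer(2, 0.68, seed=1)
        assert {l.leaflet for l in bl.lipids} == {"upper", "lower"}
        with pytest.raises(ValueError):
            cm.build_bilayer(7, 0.68, seed=1)

    def test_seeded_determinism(self):
        a = cm.build_bilayer(32, 0.68, seed=5)
        b = cm.build_bilayer(32, 0.68, seed=5)
        for la, lb in zip(a.lipids, b.lipids):
            np.testing.assert_array_equal(la.all_coords(), lb.all_coords())


class TestReferenceSurface:
    def test_periodic_and_finite(self, barrier_surface):
        dz = np.linspace(0.8, 3.0, 40)
        th = np.linspace(0.0, 360.0, 37)
        U = barrier_surface.energy(dz[:, None], th[None, :])
        assert np.all(np.isfinite(U))
        np.testing.assert_allclose(
            barrier_surface.energy(dz, 17.0), barrier_surface.energy(dz, 377.0),
            atol=1e-10)
        gz, gt = barrier_surface.gradient(dz[:, None], th[None, :])
        assert np.all(np.isfinite(gz)) and np.all(np.isfinite(gt))

    def test_barrier_preset_calibrated_by_grid_search(self, barrier_surface):
        info = barrier_surface.saddle_info
        assert info["barrier"] == pytest.approx(4.3, abs=1e-9)
        assert info["saddle"][0] == pytest.approx(1.8, abs=0.02)
        assert info["saddle"][1] == pytest.approx(150.0, abs=3.0)

    def test_gradient_matches_finite_difference(self, barrier_surface):
        rng = np.random.default_rng(0)
        dz = rng.uniform(1.0, 2.5, 50)
        th = rng.uniform(0.0, 360.0, 50)
        gz, gt = barrier_surface.gradient(dz, th)
        h = 1e-6
        gz_fd = (barrier_surface.energy(dz + h, th)
                 - barrier_surface.energy(dz - h, th)) / (2 * h)
        gt_fd = (barrier_surface.energy(dz, th + h)
                 - barrier_surface.energy(dz, th - h)) / (2 * h)
        np.testing.assert_allclose(gz, gz_fd, atol=1e-5)
        np.testing.assert_allclose(gt, gt_fd, atol=1e-5)


class TestLangevin:
    def test_flat_surface_zero_temperature_is_constant(self):
        cfg = syn.LangevinConfig(temperature=0.0, total_time=2.0,
                                 init_dz=1.8, init_dz_std=0.0, seed=1)
        traces = cm.simulate_traces(cm.ReferenceSurface.flat(), cfg, 3)
        for tr in traces:
            np.testing.assert_allclose(tr.dz, tr.dz[0], atol=1e-14)

    def test_harmonic_stationary_variance_matches_closed_form(self):
        # overdamped dynamics in 0.5*kappa*x^2 equilibrates to var = kBT/kappa
        kappa = 50.0
        surf = cm.ReferenceSurface.harmonic(kappa=kappa)
        # dt small relative to the relaxation time 1/(mobility*kappa) keeps
        # the Euler-Maruyama discretization bias well below the tolerance
        cfg = syn.LangevinConfig(total_time=100.0, dt=0.002, mobility_dz=0.1,
                                 seed=9, init_dz=1.75, init_dz_std=0.0)
        traces = cm.simulate_traces(surf, cfg, 100)
        samples = np.concatenate([tr.dz[2000:] for tr in traces])
        assert samples.var() == pytest.approx(1.0 / kappa, rel=0.02)

    def test_seeded_bit_reproducibility(self, downhill_surface):
        cfg = syn.LangevinConfig(total_time=5.0, seed=3)
        a = cm.simulate_traces(downhill_surface, cfg, 4)
        b = cm.simulate_traces(downhill_surface, cfg, 4)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.dz, tb.dz)
            np.testing.assert_array_equal(ta.theta, tb.theta)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            syn.LangevinConfig(dt=-0.1)
        with pytest.raises(ValueError):
            syn.LangevinConfig(dt=0.03, total_time=1.0)

    def test_downhill_adsorbs_within_trajectory_span(self, downhill_surface):
        cfg = syn.LangevinConfig(seed=11)
        fpts = [kin.extract_fpt(t, 1.5)
                for t in cm.simulate_traces(downhill_surface, cfg, 25)]
        finite = np.mean([not s.censored for s in fpts])
        assert finite >= 0.95

    def test_single_basin_escape_is_approximately_exponential(self):
        surf = cm.ReferenceSurface.escape_well()
        cfg = syn.LangevinConfig(seed=3, init_dz=1.75, init_dz_std=0.03)
        fpts = [kin.extract_fpt(t, 1.5) for t in cm.simulate_traces(surf, cfg, 150)]
        vals = np.array([s.value for s in fpts if not s.censored])
        cv = vals.std() / vals.mean()
        assert 0.7 < cv < 1.3
        fit = kin.fit_ccd(fpts, model="exp2", seed=0, n_starts=4)
        assert fit.degenerate  # collapses to a single exponential

    def test_barrier_preset_has_slow_tail(self, downhill_surface, barrier_surface):
        fast = [kin.extract_fpt(t, 1.5) for t in cm.simulate_traces(
            downhill_surface, syn.LangevinConfig(seed=12), 25)]
        slow = [kin.extract_fpt(t, 1.5) for t in cm.simulate_traces(
            barrier_surface, syn.LangevinConfig(seed=12), 25)]
        s_fast = np.mean([s.censored or s.value > 100.0 for s in fast])
        s_slow = np.mean([s.censored or s.value > 100.0 for s in slow])
        assert s_fast < 0.1
        assert s_slow > 0.4


class TestUmbrella:
    def test_single_window_flat_surface_centers_on_bias(self):
        ws = cm.sample_umbrella(cm.ReferenceSurface.flat(), centers=[1.7],
                                k_bias=1000.0, n_samples=4000, seed=4)
        w = ws.windows[0]
        sigma = np.sqrt(ws.kT / 1000.0)
        assert w.dz.mean() == pytest.approx(1.7, abs=5 * sigma / np.sqrt(200))

    def test_seeded_sample_streams_identical(self, downhill_surface):
        a = cm.sample_umbrella(downhill_surface, centers=np.linspace(1.0, 2.5, 8),
                               n_samples=400, seed=6)
        b = cm.sample_umbrella(downhill_surface, centers=np.linspace(1.0, 2.5, 8),
                               n_samples=400, seed=6)
        for wa, wb in zip(a.windows, b.windows):
            np.testing.assert_array_equal(wa.dz, wb.dz)
            np.testing.assert_array_equal(wa.theta, wb.theta)

    def test_centers_must_increase(self, downhill_surface):
        with pytest.raises(ValueError):
            cm.sample_umbrella(downhill_surface, centers=[1.5, 1.2], n_samples=100)


class TestContactFixture:
    def test_poisson_mean_recovered_geometrically(self, peptide_D, policy):
        mean = 1.54
        frames = cm.place_contact_fixture(peptide_D, mean, 3000, seed=3)
        counts = np.array([trp_head_contacts(f, policy) for f in frames])
        se = np.sqrt(mean / counts.size)
        assert abs(counts.mean() - mean) < 3 * se

    def test_zero_mean_gives_zero_contacts(self, peptide_D, policy):
        frames = cm.place_contact_fixture(peptide_D, 0.0, 50, seed=1)
        assert all(trp_head_contacts(f, policy) == 0 for f in frames)

    def test_negative_mean_rejected(self, peptide_D):
        with pytest.raises(ValueError):
            cm.place_contact_fixture(peptide_D, -1.0, 10, seed=0)

    def test_requires_trp(self):
        pep = cm.build_peptide("RRR")
        with pytest.raises(Exception):
            cm.place_contact_fixture(pep, 1.0, 5, seed=0)
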