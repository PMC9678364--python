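"""Morphology and kinetics readouts against constructed ground truth."""

import numpy as np
import pytest

from actoring import analysis
from actoring.analysis import (radial_density, r_median, remodeling_rate,
                               treadmilling_rate, turnover_halftime,
                               detect_clusters, local_concentration,
                               orientation_distribution,
                               mechanical_energy_series)
from actoring.state import BoundaryGeometry, Snapshot, Trajectory
from actoring.synthetic import (MorphologySpec, make_snapshot, make_event_log,
                                make_turnover_trajectory)


BND = BoundaryGeometry(diameter=4000.0, height=400.0)


def snapshot_from_points(points, bnd=BND, time=0.0):
    """Snapshot of single-monomer-pair filaments at given 2D/3D points."""
    from actoring.state import Cylinder, Filament, BARBED_FREE
    pts = np.asarray(points, dtype=float).reshape(-1, 2 if np.size(points)
                                                  and np.shape(points)[-1] == 2
                                                  else 3) \
        if np.size(points) else np.zeros((0, 3))
    if pts.shape[1] == 2:
        pts = np.hstack([pts, np.zeros((len(pts), 1))])
    filaments = {}
    for i, p in enumerate(pts):
        f = Filament(fid=i, cylinders=[
            Cylinder(p_minus=p - [1.35, 0, 0], p_plus=p + [1.35, 0, 0],
                     n_monomers=1, cid=0)], barbed_state=BARBED_FREE)
        f.L, f.R = 0, 1
        filaments[i] = f
    return Snapshot(time=time, boundary=bnd, filaments=filaments,
                    motors={}, linkers={}, grid_counts={})


class TestRadialDensity:
    def test_thin_annulus_single_bin(self):
        R = BND.effective_radius
        phi = np.linspace(0, 2 * np.pi, 500)
        # 0.52R sits mid-bin for 20 bins (no edge ties)
        pts = 0.52 * R * np.stack([np.cos(phi), np.sin(phi)], axis=1)
        prof = radial_density(snapshot_from_points(pts), n_bins=20)
        assert (prof.rho > 0).sum() == 1

    def test_uniform_disk_flat(self, rng):
        R = BND.effective_radius
        r = R * np.sqrt(rng.uniform(size=30000))
        phi = rng.uniform(0, 2 * np.pi, size=30000)
        pts = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
        prof = radial_density(snapshot_from_points(pts), n_bins=10)
        inner = prof.rho[1:-1]                 # edge bins have partial areas
        assert inner.std() / inner.mean() < 0.1

    def test_normalization(self, rng):
        pts = rng.uniform(-500, 500, size=(100, 2))
        prof = radial_density(snapshot_from_points(pts), n_bins=50)
        dr = prof.r[1] - prof.r[0]
        assert prof.rho.sum() * dr == pytest.approx(1.0)

    def test_empty_snapshot_error(self):
        snap = Snapshot(time=0, boundary=BND, filaments={}, motors={},
                        linkers={}, grid_counts={})
        with pytest.raises(ValueError):
            radial_density(snap)


class TestRMedian:
    def test_uniform_disk_analytic(self, rng):
        """Median radius of a uniform disk is R/sqrt(2)."""
        R = BND.effective_radius
        r = R * np.sqrt(rng.uniform(size=100000))
        phi = rng.uniform(0, 2 * np.pi, size=100000)
        pts = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
        assert r_median(snapshot_from_points(pts)) \
            == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_ring_at_09(self):
        R = BND.effective_radius
        phi = np.linspace(0, 2 * np.pi, 1000)
        pts = 0.9 * R * np.stack([np.cos(phi), np.sin(phi)], axis=1)
        assert r_median(snapshot_from_points(pts)) == pytest.approx(0.9, abs=1e-6)

    def test_central_mass_zero(self):
        pts = np.zeros((10, 2))
        assert r_median(snapshot_from_points(pts)) == pytest.approx(0.0, abs=1e-3)


class TestRemodelingRate:
    def test_exact_linear(self):
        t = np.arange(0, 300, 1.0)
        y = 0.4 + 0.001 * t
        assert remodeling_rate(t, y) == pytest.approx(0.001, abs=1e-6)

    def test_constant_series(self):
        t = np.arange(0, 300, 1.0)
        assert remodeling_rate(t, np.full_like(t, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_linear_then_plateau(self):
        t = np.arange(0, 400, 1.0)
        y = np.where(t < 200, 0.4 + 0.002 * t, 0.8)
        slope = remodeling_rate(t, y)
        assert slope == pytest.approx(0.002, rel=0.02)

    def test_short_series_error(self):
        with pytest.raises(ValueError):
            remodeling_rate(np.arange(5.0), np.arange(5.0))


class TestTreadmilling:
    def test_constructed_rate(self):
        """10 filaments gaining 5 monomers per 10 s -> 0.5 /s/filament."""
        traj = make_event_log(0.0, 0.0, 10, 100.0, 10.0)
        # overwrite counters deterministically: +50 per 10-s snapshot
        for k, s in enumerate(traj.snapshots):
            s.tot_be_added = 50 * k
            s.tot_pe_removed = 50 * k
        rep = treadmilling_rate(traj, t_start=0.0)
        assert rep.rtm == pytest.approx(0.5)
        assert rep.pe_rate == pytest.approx(0.5)
        assert rep.balanced

    def test_poisson_recovery(self):
        """MLE rate from Poisson counter streams recovers the truth."""
        traj = make_event_log(0.5, 0.5, 10, 1000.0, 1.0, rng=3)
        rep = treadmilling_rate(traj, t_start=0.0)
        se = np.sqrt(0.5 * 10 * 1000) / (1000 * 10)
        assert rep.rtm == pytest.approx(0.5, abs=3 * se)

    def test_balanced_log_flags_steady_state(self):
        traj = make_event_log(0.8, 0.8, 20, 500.0, 1.0, rng=4)
        rep = treadmilling_rate(traj, t_start=0.0)
        assert rep.balanced

    def test_free_filament_run_mass_action(self):
        """⟨r_TM⟩ of free filaments (large sphere, no wall contact)
        matches the mass-action prediction k_on_BE*[G] - k_off_BE computed
        from the same trajectory's mean G-actin count (within 5%)."""
        from actoring.params import Params, AVOGADRO, concentration_to_copies
        from actoring.state import (BoundaryGeometry, CompartmentGrid,
                                    NetworkState, G_ACTIN, Snapshot)
        from actoring.chemistry import ChemistryEngine
        from actoring.state import Trajectory
        bnd = BoundaryGeometry(shape="sphere", diameter=10000.0)
        params = Params()
        params.compartment_edge = 11000.0
        params.chem.k_nu = 0.0
        params.chem.k_destruction = 0.0
        st = NetworkState(boundary=bnd, grid=CompartmentGrid(bnd, 11000.0),
                          params=params)
        from conftest import make_filament
        make_filament(0, [-4000, 0, 0], [1, 0, 0], 2000, st)
        make_filament(1, [0, -4000, 0], [0, 1, 0], 2000, st)
        V = bnd.effective_volume_L
        st.grid.counts[G_ACTIN][0, 0, 0] = concentration_to_copies(0.3, V)
        eng = ChemistryEngine(st, np.random.default_rng(21))
        traj = Trajectory()
        traj.append(Snapshot.capture(st))
        for k in range(40):
            eng.advance_to(st.time + 5.0)
            traj.append(Snapshot.capture(st))
        rep = treadmilling_rate(traj, t_start=0.0)
        g_mean = np.mean([s.grid_counts[G_ACTIN].sum() for s in traj.snapshots])
        conc = g_mean / (1e-6 * AVOGADRO * V)
        chem = params.chem
        predicted = chem.k_on_BE * conc - chem.k_off_BE
        assert rep.rtm == pytest.approx(predicted, rel=0.05, abs=0.05)


class TestTurnover:
    def test_exponential_halftime(self):
        """Exponential turnover at k=0.01/s: t_1/2 = ln2/k ~ 69.3 s
        (exact quantile-spaced replacement times, so no MC noise)."""
        traj = make_turnover_trajectory(0.01, 4000, 150.0, 1.0,
                                        quantile_spacing=True)
        res = turnover_halftime(traj, label_time=0.0)
        assert not res.censored
        assert res.t_half == pytest.approx(np.log(2) / 0.01, rel=0.02)

    def test_frozen_network_censored(self):
        traj = make_turnover_trajectory(0.0, 100, 100.0, 1.0, rng=6)
        res = turnover_halftime(traj, label_time=0.0)
        assert res.censored

    def test_rate_doubling_halves_halftime(self):
        t1 = turnover_halftime(make_turnover_trajectory(0.01, 2500, 250.0, 2.0,
                                                        rng=7), 0.0).t_half
        t2 = turnover_halftime(make_turnover_trajectory(0.02, 2500, 250.0, 2.0,
                                                        rng=8), 0.0).t_half
        assert t1 / t2 == pytest.approx(2.0, rel=0.05)


def grid_snapshot(conc_map, bnd=BND):
    """Snapshot whose 100-nm-bin concentrations equal conc_map (µM)."""
    from actoring.params import AVOGADRO
    height = 2 * bnd.effective_half_height
    v_bin_L = 100.0 * 100.0 * height * 1e-24
    R = bnd.effective_radius
    pts = []
    n = conc_map.shape[0]
    for i in range(n):
        for j in range(conc_map.shape[1]):
            n_mono = int(round(conc_map[i, j] * v_bin_L * AVOGADRO * 1e-6))
            x = -R + (i + 0.5) * 100.0
            y = -R + (j + 0.5) * 100.0
            pts += [[x, y]] * n_mono
    return snapshot_from_points(pts, bnd=bnd)


class TestClusters:
    def test_block_detected(self):
        n = 38
        m = np.zeros((n, n))
        m[10:12, 10:13] = 200.0               # 2x3 block at 200 µM
        cs = detect_clusters(grid_snapshot(m))
        assert len(cs) == 1
        assert cs.clusters[0]["n_bins"] == 6
        assert cs.clusters[0]["mean_conc"] == pytest.approx(200.0, rel=0.02)

    def test_small_cluster_ignored(self):
        n = 38
        m = np.zeros((n, n))
        m[10, 10:13] = 200.0                  # only 3 bins
        assert len(detect_clusters(grid_snapshot(m))) == 0

    def test_subthreshold_gap_splits(self):
        n = 38
        m = np.zeros((n, n))
        m[10:12, 10:12] = 200.0
        m[10:12, 13:15] = 220.0               # separated by a cold column
        m[10:12, 12] = 100.0
        cs = detect_clusters(grid_snapshot(m))
        assert len(cs) == 2

    def test_matches_brute_force_labeling(self, rng):
        """scipy-based labeling equals a hand-rolled flood fill on 100
        random occupancy grids (exact cluster membership)."""
        def flood(mask):
            seen = np.zeros_like(mask, dtype=bool)
            comps = []
            for i in range(mask.shape[0]):
                for j in range(mask.shape[1]):
                    if mask[i, j] and not seen[i, j]:
                        stack = [(i, j)]
                        comp = set()
                        seen[i, j] = True
                        while stack:
                            a, b = stack.pop()
                            comp.add((a, b))
                            for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                                na, nb = a + da, b + db
                                if 0 <= na < mask.shape[0] and \
                                   0 <= nb < mask.shape[1] and \
                                   mask[na, nb] and not seen[na, nb]:
                                    seen[na, nb] = True
                                    stack.append((na, nb))
                        if len(comp) >= 4:
                            comps.append(frozenset(comp))
            return set(comps)

        for _ in range(40):
            m = np.where(rng.uniform(size=(12, 12)) < 0.35, 200.0, 0.0)
            snap = grid_snapshot(np.pad(m, 13))
            cs = detect_clusters(snap)
            got = {frozenset((i - 13, j - 13) for i, j in c["bins"])
                   for c in cs.clusters}
            assert got == flood(m >= 160.0)

    def test_local_concentration_mean(self):
        n = 38
        m = np.zeros((n, n))
        m[5:7, 5:7] = 180.0
        m[20:22, 20:22] = 220.0
        cs = detect_clusters(grid_snapshot(m))
        assert local_concentration(cs) == pytest.approx(200.0, rel=0.02)

    def test_empty_error(self):
        cs = detect_clusters(grid_snapshot(np.zeros((38, 38))))
        with pytest.raises(ValueError):
            local_concentration(cs)


class TestOrientation:
    def _ring_snapshot(self, tangential=True):
        spec = MorphologySpec(kind="ring", boundary=BND, total_monomers=8000,
                              ring_radius_frac=0.8, ring_width_nm=30.0)
        return make_snapshot(spec, 3)

    def test_tangential_ring_parallel(self):
        centers, counts = orientation_distribution(self._ring_snapshot())
        assert counts[:3].sum() / counts.sum() > 0.9

    def test_radial_spokes_perpendicular(self):
        from actoring.state import Cylinder, Filament, BARBED_FREE
        filaments = {}
        for i, phi in enumerate(np.linspace(0, 2 * np.pi, 40, endpoint=False)):
            u = np.array([np.cos(phi), np.sin(phi), 0.0])
            f = Filament(fid=i, cylinders=[
                Cylinder(p_minus=500 * u, p_plus=608 * u, n_monomers=40,
                         cid=0)], barbed_state=BARBED_FREE)
            f.L, f.R = 0, 40
            filaments[i] = f
        snap = Snapshot(time=0, boundary=BND, filaments=filaments,
                        motors={}, linkers={}, grid_counts={})
        centers, counts = orientation_distribution(snap)
        assert counts[-1] == counts.sum()

    def test_isotropic_uniform(self, rng):
        from actoring.state import Cylinder, Filament, BARBED_FREE
        filaments = {}
        for i in range(4000):
            phi = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(phi), np.sin(phi), 0.0])
            c = rng.uniform(-300, 300, size=3) * np.array([1, 1, 0])
            f = Filament(fid=i, cylinders=[
                Cylinder(p_minus=c, p_plus=c + 108 * u, n_monomers=40,
                         cid=0)], barbed_state=BARBED_FREE)
            f.L, f.R = 0, 40
            filaments[i] = f
        snap = Snapshot(time=0, boundary=BND, filaments=filaments,
                        motors={}, linkers={}, grid_counts={})
        centers, counts = orientation_distribution(snap, n_bins=9)
        frac = counts / counts.sum()
        assert frac.max() < 2.5 * frac.min() + 0.02


class TestMechanicalEnergy:
    def test_definition_excludes_boundary(self):
        snaps = []
        for k in range(3):
            s = snapshot_from_points([[0, 0]], time=float(k))
            s.energy = {"U_fil_bend": 10.0, "U_fil_str": 5.0,
                        "U_motor_str": 3.0, "U_linker_str": 2.0,
                        "U_boundary": 7.0}
            snaps.append(s)
        traj = Trajectory()
        for s in snaps:
            if traj.snapshots and s.time <= traj.snapshots[-1].time:
                s.time += 0.5
            traj.append(s)
        t, u, mean = mechanical_energy_series(traj)
        assert np.allclose(u, 20.0)
        assert mean == pytest.approx(20.0)

    def test_missing_breakdown_error(self):
        traj = Trajectory()
        traj.append(snapshot_from_points([[0, 0]]))
        with pytest.raises(ValueError):
            mechanical_energy_series(traj)
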