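"""Reaction operations, conservation laws, binding-pair search, and the
event-driven engine against analytic kinetics."""

import numpy as np
import pytest

from actoring import chemistry as C
from actoring.chemistry import (polymerize, depolymerize, nucleate_step1,
                                nucleate_step2, formin_dissociate,
                                destroy_filament, find_binding_pairs,
                                bind_motor, bind_linker, motor_walk,
                                next_site_toward_barbed, ChemistryEngine,
                                BindingPairCandidate)
from actoring.state import (G_ACTIN, FORMIN, INTERMEDIATE, NMII, LINKER,
                            BARBED_FORMIN, BARBED_FREE, BindingSite,
                            CompartmentGrid, NetworkState, validate_state)
from actoring.params import Params
from conftest import make_filament


def put(state, species, n, comp=(0, 0, 0)):
    state.grid.counts[species][comp] += n


class TestPolymerize:
    def test_grows_cylinder(self, empty_state):
        f = make_filament(0, [0, 0, 0], [1, 0, 0], 39, empty_state)
        put(empty_state, G_ACTIN, 5)
        polymerize(empty_state, 0, "BE")
        assert f.cylinders[-1].n_monomers == 40
        assert empty_state.grid.total(G_ACTIN) == 4
        assert f.be_added == 1

    def test_full_cylinder_spawns_collinear(self, empty_state):
        f = make_filament(0, [0, 0, 0], [1, 0, 0], 40, empty_state)
        put(empty_state, G_ACTIN, 1)
        polymerize(empty_state, 0, "BE")
        assert len(f.cylinders) == 2
        nc = f.cylinders[-1]
        assert nc.n_monomers == 1
        assert np.allclose(nc.axis, f.cylinders[0].axis)
        assert np.allclose(nc.p_minus, f.cylinders[0].p_plus)

    def test_pointed_end_extends_backwards(self, empty_state):
        f = make_filament(0, [0, 0, 0], [1, 0, 0], 30, empty_state)
        put(empty_state, G_ACTIN, 1)
        p0 = f.pointed_cylinder.p_minus.copy()
        polymerize(empty_state, 0, "PE")
        assert f.pointed_cylinder.n_monomers == 31
        assert np.allclose(f.pointed_cylinder.p_minus, p0 - 2.7 * np.array([1, 0, 0]))

    def test_no_g_actin_rejected(self, empty_state):
        make_filament(0, [0, 0, 0], [1, 0, 0], 30, empty_state)
        with pytest.raises(ValueError):
            polymerize(empty_state, 0, "BE")


class TestDepolymerize:
    def test_shrinks_end(self, empty_state):
        f = make_filament(0, [0, 0, 0], [1, 0, 0], 41, empty_state)
        depolymerize(empty_state, 0, "PE")
        assert f.n_monomers == 40
        assert empty_state.grid.total(G_ACTIN) == 1
        assert f.pe_removed == 1

    def test_three_monomer_leaves_destruction_eligible(self, empty_state):
        f = make_filament(0, [0, 0, 0], [1, 0, 0], 3, empty_state)
        depolymerize(empty_state, 0, "BE")
        assert f.n_monomers == 2

    def test_two_monomer_rejected(self, empty_state):
        make_filament(0, [0, 0, 0], [1, 0, 0], 2, empty_state)
        with pytest.raises(ValueError):
            depolymerize(empty_state, 0, "BE")

    def test_empty_cylinder_removed(self, empty_state):
        f = make_filament(0, [0, 0, 0], [1, 0, 0], 41, empty_state)
        assert len(f.cylinders) == 2
        depolymerize(empty_state, 0, "BE")
        assert len(f.cylinders) == 1

    def test_mixed_events_conserve_monomers(self, empty_state, rng):
        """Exact actin bookkeeping across 10^4 random poly/depoly events."""
        make_filament(0, [-500, 0, 0], [1, 0, 0], 100, empty_state)
        make_filament(1, [-500, 50, 0], [1, 0, 0], 100, empty_state)
        put(empty_state, G_ACTIN, 5000)
        total0 = empty_state.total_actin()
        for _ in range(10000):
            fid = int(rng.integers(2))
            end = "BE" if rng.uniform() < 0.5 else "PE"
            f = empty_state.filaments[fid]
            if rng.uniform() < 0.5 and empty_state.grid.total(G_ACTIN) > 0:
                polymerize(empty_state, fid, end)
            elif f.n_monomers > 2:
                depolymerize(empty_state, fid, end)
            assert empty_state.total_actin() == total0
        assert validate_state(empty_state) == []


class TestNucleation:
    def test_stoichiometry(self, empty_state, rng):
        put(empty_state, FORMIN, 1)
        put(empty_state, G_ACTIN, 3)
        nucleate_step1(empty_state, (0, 0, 0))
        assert empty_state.grid.total(INTERMEDIATE) == 1
        fid = nucleate_step2(empty_state, (0, 0, 0), rng)
        assert fid is not None
        f = empty_state.filaments[fid]
        assert f.n_monomers == 3
        assert f.barbed_state == BARBED_FORMIN
        assert empty_state.grid.total(G_ACTIN) == 0
        assert empty_state.grid.total(FORMIN) == 0

    def test_formin_conserved_over_cycles(self, empty_state, rng):
        """Total formin (free + intermediate + FBE-bound) is exact over
        1000 nucleation/dissociation/destruction cycles."""
        put(empty_state, FORMIN, 10)
        put(empty_state, G_ACTIN, 5000)
        total0 = empty_state.total_formin()
        actin0 = empty_state.total_actin()
        for _ in range(1000):
            comp = (0, 0, 0)
            g = empty_state.grid.counts
            if g[FORMIN][comp] > 0 and g[G_ACTIN][comp] >= 3:
                nucleate_step1(empty_state, comp)
                nucleate_step2(empty_state, comp, rng)
            fids = list(empty_state.filaments)
            if fids:
                fid = fids[int(rng.integers(len(fids)))]
                f = empty_state.filaments[fid]
                if f.barbed_state == BARBED_FORMIN and rng.uniform() < 0.5:
                    formin_dissociate(empty_state, fid)
                if f.n_monomers > 2 and rng.uniform() < 0.7:
                    depolymerize(empty_state, fid, "PE")
                if f.n_monomers == 2:
                    destroy_filament(empty_state, fid)
            assert empty_state.total_formin() == total0
            assert empty_state.total_actin() == actin0

    def test_poisson_mean_step1_events(self):
        """k_nu = 0.005/s per eligible formin: 100 formins for 100 s give
        50 step-1 firings on average (Poisson)."""
        rates = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n_formin = 100
            t = 0.0
            events = 0
            while True:
                a = 0.005 * n_formin
                t += rng.exponential(1.0 / a)
                if t > 100.0:
                    break
                events += 1
            rates.append(events)
        mean = np.mean(rates)
        se = np.std(rates) / np.sqrt(len(rates))
        assert abs(mean - 50.0) < 3 * se + 1e-9


class TestForminDissociation:
    def test_releases_formin(self, empty_state):
        f = make_filament(0, [0, 0, 0], [1, 0, 0], 30, empty_state)
        f.barbed_state = BARBED_FORMIN
        formin_dissociate(empty_state, 0)
        assert f.barbed_state == BARBED_FREE
        assert empty_state.grid.total(FORMIN) == 1

    def test_free_barbed_end_rejected(self, empty_state):
        make_filament(0, [0, 0, 0], [1, 0, 0], 30, empty_state)
        with pytest.raises(ValueError):
            formin_dissociate(empty_state, 0)

    def test_exponential_survival(self):
        """200 formin-capped ends at k_off=0.01/s: ~126 dissociate in 100 s
        (1 - e^-1 survival)."""
        rng = np.random.default_rng(5)
        n = 0
        for _ in range(200):
            if rng.exponential(1.0 / 0.01) <= 100.0:
                n += 1
        assert abs(n - 200 * (1 - np.exp(-1))) < 3 * np.sqrt(200 * 0.632 * 0.368)


class TestDestruction:
    def test_two_monomer_destroyed(self, empty_state):
        make_filament(0, [0, 0, 0], [1, 0, 0], 2, empty_state)
        destroy_filament(empty_state, 0)
        assert 0 not in empty_state.filaments
        assert empty_state.grid.total(G_ACTIN) == 2

    def test_longer_filament_rejected(self, empty_state):
        make_filament(0, [0, 0, 0], [1, 0, 0], 3, empty_state)
        with pytest.raises(ValueError):
            destroy_filament(empty_state, 0)

    def test_bound_elements_force_released(self, empty_state):
        from actoring.state import MotorEnsemble
        f = make_filament(0, [0, 0, 0], [1, 0, 0], 2, empty_state)
        make_filament(1, [0, 200, 0], [1, 0, 0], 80, empty_state)
        empty_state.motors[0] = MotorEnsemble(
            mid=0, n_heads=20,
            site_a=BindingSite(0, f.cylinders[0].cid, 0),
            site_b=BindingSite(1, empty_state.filaments[1].cylinders[0].cid, 0),
            eq_length=200.0)
        released = destroy_filament(empty_state, 0)
        assert ("motor", 0) in released
        assert empty_state.grid.total(NMII) == 1
        assert not empty_state.motors


class TestBindingPairSearch:
    def test_window_membership(self, empty_state):
        # short parallel filaments 200 nm apart: inside the motor span
        # window, far outside the linker window
        make_filament(0, [-54, 0, 0], [1, 0, 0], 40, empty_state)
        make_filament(1, [-54, 200, 0], [1, 0, 0], 40, empty_state)
        assert len(find_binding_pairs(empty_state, "motor")) > 0
        assert find_binding_pairs(empty_state, "linker") == []

    def test_close_filaments_linker_only(self, empty_state):
        make_filament(0, [-54, 0, 0], [1, 0, 0], 40, empty_state)
        make_filament(1, [-54, 35, 0], [1, 0, 0], 40, empty_state)
        assert len(find_binding_pairs(empty_state, "linker")) > 0
        assert find_binding_pairs(empty_state, "motor") == []

    def test_same_filament_excluded(self, empty_state):
        # a bent filament could offer intra-filament pairs; none allowed
        f = make_filament(0, [-200, 0, 0], [1, 0, 0], 160, empty_state)
        assert find_binding_pairs(empty_state, "linker") == []
        assert find_binding_pairs(empty_state, "motor") == []

    def test_occupied_sites_excluded(self, empty_state, rng):
        make_filament(0, [-200, 0, 0], [1, 0, 0], 160, empty_state)
        make_filament(1, [-200, 35, 0], [1, 0, 0], 160, empty_state)
        put(empty_state, LINKER, 10)
        pairs = find_binding_pairs(empty_state, "linker")
        bind_linker(empty_state, pairs[0], rng)
        pairs2 = find_binding_pairs(empty_state, "linker")
        assert all(p.site_a not in empty_state.linker_sites
                   and p.site_b not in empty_state.linker_sites for p in pairs2)

    def test_matches_brute_force(self, empty_state, rng):
        """k-d tree search equals the O(n^2) scan on 20 random filaments."""
        for i in range(20):
            p0 = rng.uniform(-400, 400, size=3) * np.array([1, 1, 0.2])
            d = rng.normal(size=3) * np.array([1, 1, 0.1])
            make_filament(i, p0, d, int(rng.integers(40, 200)), empty_state)
        for sp in ("motor", "linker"):
            fast = {(c.site_a, c.site_b)
                    for c in find_binding_pairs(empty_state, sp)}
            slow = {(c.site_a, c.site_b)
                    for c in find_binding_pairs(empty_state, sp,
                                                brute_force=True)}
            assert fast == slow
            assert len(fast) > 0


class TestMotorBindingWalking:
    def _two_filaments(self, state):
        make_filament(0, [-200, 0, 0], [1, 0, 0], 300, state)
        make_filament(1, [-200, 200, 0], [1, 0, 0], 300, state)

    def test_bind_zero_initial_energy(self, empty_state, rng):
        from actoring.mechanics import spring_energy
        self._two_filaments(empty_state)
        put(empty_state, NMII, 3)
        pairs = find_binding_pairs(empty_state, "motor")
        mid = bind_motor(empty_state, pairs[0], 20, rng)
        m = empty_state.motors[mid]
        assert m.eq_length == pytest.approx(pairs[0].distance)
        assert spring_energy(m, empty_state) == pytest.approx(0.0, abs=1e-9)
        assert empty_state.grid.total(NMII) == 2

    def test_nmii_conserved_over_bind_unbind(self, empty_state, rng):
        self._two_filaments(empty_state)
        put(empty_state, NMII, 5)
        for _ in range(50):
            pairs = find_binding_pairs(empty_state, "motor")
            if pairs and empty_state.grid.total(NMII) > 0:
                bind_motor(empty_state, pairs[int(rng.integers(len(pairs)))],
                           int(rng.integers(15, 31)), rng)
            if empty_state.motors and rng.uniform() < 0.5:
                mid = list(empty_state.motors)[0]
                C.unbind_motor(empty_state, mid)
            assert empty_state.total_nmii() == 5

    def test_walk_advances_toward_barbed(self, empty_state, rng):
        self._two_filaments(empty_state)
        put(empty_state, NMII, 1)
        pairs = find_binding_pairs(empty_state, "motor")
        mid = bind_motor(empty_state, pairs[0], 20, rng)
        m = empty_state.motors[mid]
        old = m.site_a
        moved = motor_walk(empty_state, mid, "a")
        assert moved
        new = m.site_a
        # strictly later in (cylinder, site) order toward the barbed end
        f = empty_state.filaments[new.fid]
        assert (f.cylinder_index(new.cid), new.site_index) \
            > (f.cylinder_index(old.cid), old.site_index)

    def test_walk_blocked_at_barbed_most_site(self, empty_state, rng):
        self._two_filaments(empty_state)
        f = empty_state.filaments[0]
        last = BindingSite(0, f.cylinders[-1].cid, 3)
        assert next_site_toward_barbed(empty_state, last) is None

    def test_walk_builds_tension(self, empty_state, rng):
        """Stepping keeps the binding-time rest length, so moving an
        attachment site stretches the ensemble spring (the origin of
        contractile force)."""
        self._two_filaments(empty_state)
        put(empty_state, NMII, 1)
        pairs = find_binding_pairs(empty_state, "motor")
        mid = bind_motor(empty_state, pairs[0], 20, rng)
        m = empty_state.motors[mid]
        l0 = m.eq_length
        motor_walk(empty_state, mid, "a")
        assert m.eq_length == l0
        pa = empty_state.site_position(m.site_a)
        pb = empty_state.site_position(m.site_b)
        l_new = float(np.linalg.norm(pb - pa))
        assert l_new != pytest.approx(l0)


class TestEngineKinetics:
    def test_barbed_elongation_rate_mass_action(self, empty_state):
        """Free-filament barbed-end gross elongation matches k_on*[G]
        (ratchet off away from walls): Poisson rate estimate within 3 SE."""
        make_filament(0, [-400, 0, 0], [1, 0, 0], 100, empty_state)
        # disable everything but BE polymerization
        ch = empty_state.params.chem
        ch.k_off_BE = ch.k_off_PE = ch.k_on_PE = 0.0
        ch.k_nu = ch.k_destruction = 0.0
        put(empty_state, G_ACTIN, 20000)
        rng = np.random.default_rng(11)
        eng = ChemistryEngine(empty_state, rng)
        conc0 = eng.conc(G_ACTIN, (0, 0, 0))
        # short window so the tip stays far from the confining wall and
        # pool depletion is ~1%
        T = 0.3
        eng.advance_to(T)
        f = empty_state.filaments[0]
        expected = ch.k_on_BE * conc0 * T
        assert f.be_added == pytest.approx(expected,
                                           abs=3 * np.sqrt(expected) + 0.02 * expected)

    def test_engine_conserves_everything(self, empty_state, rng):
        """Full engine run: actin, formin, NMII and linker totals exact."""
        for i in range(6):
            p0 = rng.uniform(-300, 300, size=3) * np.array([1, 1, 0.1])
            make_filament(i, p0, rng.normal(size=3) * np.array([1, 1, 0.1]),
                          150, empty_state)
        put(empty_state, G_ACTIN, 3000)
        put(empty_state, FORMIN, 20)
        put(empty_state, NMII, 10)
        put(empty_state, LINKER, 200)
        a0 = empty_state.total_actin()
        f0 = empty_state.total_formin()
        m0 = empty_state.total_nmii()
        l0 = empty_state.total_linker()
        eng = ChemistryEngine(empty_state, np.random.default_rng(42))
        for k in range(10):
            eng.advance_to(empty_state.time + 2.0)
            eng.rebuild()
            assert empty_state.total_actin() == a0
            assert empty_state.total_formin() == f0
            assert empty_state.total_nmii() == m0
            assert empty_state.total_linker() == l0
        assert eng.n_events > 1000
        assert validate_state(empty_state) == []

    def test_unloaded_walk_velocity(self, empty_state):
        """Mean unloaded ensemble velocity = k_walk0 x site spacing."""
        make_filament(0, [-600, 0, 0], [1, 0, 0], 400, empty_state)
        make_filament(1, [-600, 200, 0], [1, 0, 0], 400, empty_state)
        ch = empty_state.params.chem
        for name in ("k_on_BE", "k_on_PE", "k_off_BE", "k_off_PE", "k_nu",
                     "k_destruction", "k_off_linker", "k_on_linker"):
            setattr(ch, name, 0.0)
        ch.k_off_head = 0.0                      # motors stay bound
        ch.k_on_head = 0.0
        put(empty_state, NMII, 1)
        rng = np.random.default_rng(3)
        pairs = find_binding_pairs(empty_state, "motor")
        mid = bind_motor(empty_state, pairs[0], 20, rng)
        eng = ChemistryEngine(empty_state, rng)
        m = empty_state.motors[mid]
        f = empty_state.filaments[m.site_a.fid]
        start_pos = empty_state.site_position(m.site_a).copy()
        T = 5.0
        eng.advance_to(T)
        moved = float(np.linalg.norm(
            empty_state.site_position(m.site_a) - start_pos))
        site_spacing = 0.25 * f.cylinders[0].length
        expected = ch.k_walk0 * site_spacing * T
        # the a-end walks at k_walk0 steps/s, 27 nm site spacing
        assert moved == pytest.approx(expected, rel=0.35)


class TestDiffusionEngine:
    def _grid_state(self, edges=500.0):
        from actoring.state import BoundaryGeometry
        bnd = BoundaryGeometry(diameter=2000.0, height=400.0)
        params = Params()
        params.compartment_edge = edges
        return NetworkState(boundary=bnd, grid=CompartmentGrid(bnd, edges),
                            params=params)

    def test_two_compartment_equilibration(self):
        """Closed symmetric pair: long-run occupancy 50/50."""
        st = self._grid_state(1000.0)
        st.params.chem.D_diff = 1.0e6           # slow hops, fewer events
        st.grid.counts[G_ACTIN][0, 0, 0] = 200
        eng = ChemistryEngine(st, np.random.default_rng(8))
        counts = []
        for _ in range(200):
            eng.advance_to(st.time + 0.01)
            counts.append(st.grid.counts[G_ACTIN][0, 0, 0])
        mean = np.mean(counts[50:])
        frac = mean / 200
        assert abs(frac - 1.0 / st.grid.n_compartments) < 0.1
        assert st.grid.total(G_ACTIN) == 200

    def test_uniform_equilibrium_profile(self):
        """Symmetric random walk on the grid: stationary occupancy uniform
        (chi-squared test on the time-averaged profile)."""
        st = self._grid_state(500.0)
        st.params.chem.D_diff = 2.0e6          # ~8 hops/s per molecule
        st.grid.counts[G_ACTIN][0, 0, 0] = 400   # all in one corner
        eng = ChemistryEngine(st, np.random.default_rng(9))
        acc = np.zeros_like(st.grid.counts[G_ACTIN], dtype=float)
        n_samp = 0
        for k in range(600):
            eng.advance_to(st.time + 0.01)
            if k >= 300:                       # ~25 hops/molecule burn-in
                acc += st.grid.counts[G_ACTIN]
                n_samp += 1
        profile = (acc / n_samp).ravel()
        expected = 400 / st.grid.n_compartments
        # loose band: time-averaged samples are correlated
        assert profile.min() > 0.5 * expected
        assert profile.max() < 2.0 * expected
        assert st.grid.total(G_ACTIN) == 400
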