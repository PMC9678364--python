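"""Stochastic actomyosin chemistry: reaction operations and the NRM engine.

Reaction channels (all exact, event-driven):

- diffusion hops between neighboring compartments
- polymerization / depolymerization at barbed (BE) and pointed (PE) ends
- two-step formin nucleation (step 1 rate-limiting, step 2 fast)
- formin dissociation from the barbed end (FBE -> BE)
- destruction of 2-monomer filaments back to 2 G-actin
- motor-ensemble and crosslinker binding over geometric site-pair
  candidates, force-dependent unbinding, and motor walking

Module-level functions implement the individual state mutations (and are
unit-testable in isolation); :class:`ChemistryEngine` assembles them into
a Next-Reaction-Method event loop. Force-dependent rate factors are fixed
for the duration of one chemistry window and refreshed by the protocol
driver after each energy minimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nrm import NRMQueue, ChemicallyFrozen, INF
from .params import MONOMER_SIZE, MAX_MONOMERS_PER_CYLINDER, AVOGADRO
from .state import (NetworkState, Filament, Cylinder, BindingSite,
                    MotorEnsemble, Linker,
                    G_ACTIN, FORMIN, INTERMEDIATE, NMII, LINKER,
                    BARBED_FREE, BARBED_FORMIN)
from . import mechanochem


# ---------------------------------------------------------------------------
# elementary state mutations

def diffusion_hop(state: NetworkState, species: str, src: tuple, dst: tuple) -> None:
    """Transfer one molecule to a neighboring compartment."""
    state.grid.hop(species, src, dst)


def _tip_compartment(state: NetworkState, f: Filament, end: str) -> tuple:
    p = f.barbed_cylinder.p_plus if end == "BE" else f.pointed_cylinder.p_minus
    return state.grid.index_of(p)


def polymerize(state: NetworkState, fid: int, end: str) -> None:
    """Add one monomer at the given end, consuming local G-actin.

    The end cylinder grows by 2.7 nm along its axis; a full (40-monomer)
    cylinder spawns a new collinear 1-monomer cylinder.
    """
    f = state.filaments[fid]
    comp = _tip_compartment(state, f, end)
    if state.grid.counts[G_ACTIN][comp] < 1:
        raise ValueError("no local G-actin to polymerize")
    state.grid.counts[G_ACTIN][comp] -= 1
    if end == "BE":
        c = f.barbed_cylinder
        u = c.axis
        if c.n_monomers < MAX_MONOMERS_PER_CYLINDER:
            c.p_plus = c.p_plus + MONOMER_SIZE * u
            c.n_monomers += 1
        else:
            nc = Cylinder(p_minus=c.p_plus.copy(),
                          p_plus=c.p_plus + MONOMER_SIZE * u,
                          n_monomers=1, cid=f.new_cid())
            f.cylinders.append(nc)
        f.R += 1
        f.be_added += 1
        state.tot_be_added += 1
    elif end == "PE":
        c = f.pointed_cylinder
        u = c.axis
        if c.n_monomers < MAX_MONOMERS_PER_CYLINDER:
            c.p_minus = c.p_minus - MONOMER_SIZE * u
            c.n_monomers += 1
        else:
            nc = Cylinder(p_minus=c.p_minus - MONOMER_SIZE * u,
                          p_plus=c.p_minus.copy(),
                          n_monomers=1, cid=f.new_cid())
            f.cylinders.insert(0, nc)
        f.L -= 1
        f.pe_added += 1
        state.tot_pe_added += 1
    else:
        raise ValueError(f"unknown end {end!r}")


def depolymerize(state: NetworkState, fid: int, end: str) -> list:
    """Remove one monomer from the given end, releasing G-actin locally.

    Returns a list of ("motor"|"linker", id) elements force-released
    because their host cylinder vanished. Rejected on 2-monomer filaments
    (the destruction channel owns that state).
    """
    f = state.filaments[fid]
    if f.n_monomers <= 2:
        raise ValueError("cannot depolymerize a 2-monomer filament")
    comp = _tip_compartment(state, f, end)
    released: list = []
    if end == "BE":
        c = f.barbed_cylinder
        u = c.axis
        c.p_plus = c.p_plus - MONOMER_SIZE * u
        c.n_monomers -= 1
        if c.n_monomers == 0:
            released = _release_on_cylinder(state, fid, c.cid)
            f.cylinders.pop()
        f.R -= 1
        f.be_removed += 1
        state.tot_be_removed += 1
    elif end == "PE":
        c = f.pointed_cylinder
        u = c.axis
        c.p_minus = c.p_minus + MONOMER_SIZE * u
        c.n_monomers -= 1
        if c.n_monomers == 0:
            released = _release_on_cylinder(state, fid, c.cid)
            f.cylinders.pop(0)
        f.L += 1
        f.pe_removed += 1
        state.tot_pe_removed += 1
    else:
        raise ValueError(f"unknown end {end!r}")
    state.grid.counts[G_ACTIN][comp] += 1
    return released


def _release_on_cylinder(state: NetworkState, fid: int, cid: int) -> list:
    released = []
    for mid, m in list(state.motors.items()):
        if (m.site_a.fid == fid and m.site_a.cid == cid) or \
           (m.site_b.fid == fid and m.site_b.cid == cid):
            unbind_motor(state, mid)
            released.append(("motor", mid))
    for lid, l in list(state.linkers.items()):
        if (l.site_a.fid == fid and l.site_a.cid == cid) or \
           (l.site_b.fid == fid and l.site_b.cid == cid):
            unbind_linker(state, lid)
            released.append(("linker", lid))
    return released


def nucleate_step1(state: NetworkState, comp: tuple) -> None:
    """Formin + G-actin -> intermediate (rate-limiting step)."""
    g = state.grid.counts
    if g[FORMIN][comp] < 1 or g[G_ACTIN][comp] < 1:
        raise ValueError("nucleation step 1 requires formin and G-actin")
    g[FORMIN][comp] -= 1
    g[G_ACTIN][comp] -= 1
    g[INTERMEDIATE][comp] += 1


def nucleate_step2(state: NetworkState, comp: tuple,
                   rng: np.random.Generator, max_tries: int = 50) -> int | None:
    """Intermediate + G-actin -> 3-monomer filament (fast step).

    The intermediate carries one actin; two further G-actin are consumed
    so that the 3-monomer product (PE-actin, F-actin, FBE-actin) exactly
    conserves the total monomer count. Places the new formin-capped
    filament at a uniformly random position and orientation inside
    compartment ∩ effective boundary. Returns the new filament id, or
    None if placement failed after bounded retries (the intermediate and
    the G-actin then stay in the pool).
    """
    g = state.grid.counts
    if g[INTERMEDIATE][comp] < 1 or g[G_ACTIN][comp] < 2:
        raise ValueError("nucleation step 2 requires intermediate and 2 G-actin")
    bnd = state.boundary
    grid = state.grid
    lo = grid.origin + np.array(comp) * grid.edge
    hi = lo + grid.edge
    # clip the sampling box to the effective-boundary bounding box so the
    # acceptance probability stays high even for coarse compartments
    R = bnd.effective_radius
    z_half = bnd.effective_half_height if bnd.shape == "oblate" else R
    lo = np.maximum(lo, [-R, -R, -z_half])
    hi = np.minimum(hi, [R, R, z_half])
    if np.any(hi <= lo):
        return None
    length = 3 * MONOMER_SIZE
    for _ in range(max_tries):
        center = rng.uniform(lo, hi)
        if not bnd.inside_effective(center):
            continue
        u = _random_orientation(bnd, rng)
        p0 = center - 0.5 * length * u
        p1 = center + 0.5 * length * u
        if bnd.inside_effective(p0) and bnd.inside_effective(p1):
            g[INTERMEDIATE][comp] -= 1
            g[G_ACTIN][comp] -= 2
            fid = state.new_fid()
            f = Filament(fid=fid, cylinders=[], barbed_state=BARBED_FORMIN)
            f.cylinders = [Cylinder(p_minus=p0, p_plus=p1, n_monomers=3,
                                    cid=f.new_cid())]
            f.L, f.R = 0, 3
            state.filaments[fid] = f
            return fid
    return None


def _random_orientation(bnd, rng) -> np.ndarray:
    if bnd.shape == "sphere":
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    # oblate: uniform in-plane azimuth with +-5 degree polar jitter to
    # avoid an exactly planar degenerate configuration
    phi = rng.uniform(0, 2 * np.pi)
    tilt = rng.uniform(-np.deg2rad(5), np.deg2rad(5))
    return np.array([np.cos(phi) * np.cos(tilt),
                     np.sin(phi) * np.cos(tilt),
                     np.sin(tilt)])


def formin_dissociate(state: NetworkState, fid: int) -> None:
    """FBE -> BE, releasing a diffusing formin at the barbed end."""
    f = state.filaments[fid]
    if f.barbed_state != BARBED_FORMIN:
        raise ValueError("filament barbed end carries no formin")
    f.barbed_state = BARBED_FREE
    comp = _tip_compartment(state, f, "BE")
    state.grid.counts[FORMIN][comp] += 1


def destroy_filament(state: NetworkState, fid: int) -> list:
    """Remove a 2-monomer filament, releasing 2 G-actin (and any bound
    motors/linkers, returned as forced-unbinding records)."""
    f = state.filaments[fid]
    if f.n_monomers != 2:
        raise ValueError("destruction applies only to 2-monomer filaments")
    released = []
    for c in list(f.cylinders):
        released += _release_on_cylinder(state, fid, c.cid)
    comp = _tip_compartment(state, f, "BE")
    if f.barbed_state == BARBED_FORMIN:
        # formin-capped dimers release their formin with destruction
        state.grid.counts[FORMIN][comp] += 1
    state.grid.counts[G_ACTIN][comp] += 2
    del state.filaments[fid]
    return released


# ---------------------------------------------------------------------------
# binding-pair search

@dataclass(frozen=True)
class BindingPairCandidate:
    site_a: BindingSite
    site_b: BindingSite
    distance: float


def iter_sites(state: NetworkState):
    for fid in sorted(state.filaments):
        f = state.filaments[fid]
        for c in f.cylinders:
            for si in range(len(state.params.binding_site_fractions)):
                yield BindingSite(fid, c.cid, si)


def _all_site_positions(state: NetworkState):
    """Vectorized (sites, positions) over every binding site in the state."""
    sites = []
    chunks = []
    fracs = np.asarray(state.params.binding_site_fractions)
    for fid in sorted(state.filaments):
        f = state.filaments[fid]
        for c in f.cylinders:
            for si in range(len(fracs)):
                sites.append(BindingSite(fid, c.cid, si))
            chunks.append((1 - fracs)[:, None] * c.p_minus[None, :]
                          + fracs[:, None] * c.p_plus[None, :])
    if not sites:
        return [], np.zeros((0, 3))
    return sites, np.concatenate(chunks, axis=0)


def _pair_index_arrays(state: NetworkState, species: str):
    """(sites, positions, pair index array, distances) for unoccupied
    site pairs on distinct filaments within the species span window."""
    from scipy.spatial import cKDTree
    lo, hi = state.params.motor_span if species == "motor" else state.params.linker_span
    occupied = state.motor_sites if species == "motor" else state.linker_sites
    sites, pos = _all_site_positions(state)
    if not sites:
        return sites, pos, np.zeros((0, 2), dtype=np.int64), np.zeros(0)
    free = np.array([s not in occupied for s in sites], dtype=bool)
    idx_free = np.nonzero(free)[0]
    if len(idx_free) == 0:
        return sites, pos, np.zeros((0, 2), dtype=np.int64), np.zeros(0)
    fids = np.array([s.fid for s in sites], dtype=np.int64)
    tree = cKDTree(pos[idx_free])
    raw = tree.query_pairs(hi, output_type="ndarray")
    if len(raw) == 0:
        return sites, pos, np.zeros((0, 2), dtype=np.int64), np.zeros(0)
    pairs = idx_free[raw]
    d = np.sqrt(np.sum((pos[pairs[:, 0]] - pos[pairs[:, 1]]) ** 2, axis=1))
    keep = (d >= lo) & (fids[pairs[:, 0]] != fids[pairs[:, 1]])
    pairs = pairs[keep]
    d = d[keep]
    swap = pairs[:, 0] > pairs[:, 1]
    pairs[swap] = pairs[swap][:, ::-1]
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return sites, pos, pairs[order], d[order]


def find_binding_pairs(state: NetworkState, species: str,
                       brute_force: bool = False) -> list:
    """All unoccupied site pairs on distinct filaments within the span
    window of the species ("motor": 175-225 nm, "linker": 30-40 nm).

    Uses a k-d tree neighbor query with radius = window max; set
    ``brute_force`` for the O(n^2) reference scan. Deterministic order.
    """
    if brute_force:
        lo, hi = (state.params.motor_span if species == "motor"
                  else state.params.linker_span)
        occupied = state.motor_sites if species == "motor" else state.linker_sites
        all_sites, all_pos = _all_site_positions(state)
        keep = [i for i, s in enumerate(all_sites) if s not in occupied]
        sites = [all_sites[i] for i in keep]
        pos = all_pos[keep] if keep else all_pos
        out = []
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                if sites[i].fid == sites[j].fid:
                    continue
                d = float(np.linalg.norm(pos[i] - pos[j]))
                if lo <= d <= hi:
                    out.append(BindingPairCandidate(sites[i], sites[j], d))
        return out
    sites, pos, pairs, dist = _pair_index_arrays(state, species)
    return [BindingPairCandidate(sites[i], sites[j], float(d))
            for (i, j), d in zip(pairs, dist)]


# ---------------------------------------------------------------------------
# motor / linker binding, unbinding, walking

def _take_from_pool(state: NetworkState, species: str, near: np.ndarray,
                    rng: np.random.Generator) -> tuple:
    """Remove one copy of a diffusing species, preferring the compartment
    containing ``near``; falls back to a count-weighted random compartment."""
    grid = state.grid
    comp = grid.index_of(near)
    if grid.counts[species][comp] >= 1:
        grid.counts[species][comp] -= 1
        return comp
    flat = grid.counts[species].ravel()
    total = flat.sum()
    if total < 1:
        raise ValueError(f"no free {species} available")
    idx = rng.choice(len(flat), p=flat / total)
    ijk = np.unravel_index(idx, grid.counts[species].shape)
    grid.counts[species][ijk] -= 1
    return tuple(int(v) for v in ijk)


def bind_motor(state: NetworkState, pair: BindingPairCandidate, n_heads: int,
               rng: np.random.Generator) -> int:
    """Bind an NMII ensemble across a candidate pair; eq_length is the
    current site separation (zero initial stretching energy)."""
    mid = state.new_mid()
    pa = state.site_position(pair.site_a)
    pb = state.site_position(pair.site_b)
    _take_from_pool(state, NMII, 0.5 * (pa + pb), rng)
    state.motors[mid] = MotorEnsemble(mid=mid, n_heads=n_heads,
                                      site_a=pair.site_a, site_b=pair.site_b,
                                      eq_length=float(np.linalg.norm(pb - pa)))
    state.motor_sites.add(pair.site_a)
    state.motor_sites.add(pair.site_b)
    return mid


def bind_linker(state: NetworkState, pair: BindingPairCandidate,
                rng: np.random.Generator) -> int:
    lid = state.new_lid()
    pa = state.site_position(pair.site_a)
    pb = state.site_position(pair.site_b)
    _take_from_pool(state, LINKER, 0.5 * (pa + pb), rng)
    state.linkers[lid] = Linker(lid=lid, site_a=pair.site_a, site_b=pair.site_b,
                                eq_length=float(np.linalg.norm(pb - pa)))
    state.linker_sites.add(pair.site_a)
    state.linker_sites.add(pair.site_b)
    return lid


def unbind_motor(state: NetworkState, mid: int) -> None:
    m = state.motors.pop(mid)
    state.motor_sites.discard(m.site_a)
    state.motor_sites.discard(m.site_b)
    try:
        pa = state.site_position(m.site_a)
        comp = state.grid.index_of(pa)
    except KeyError:
        comp = (0, 0, 0)
    state.grid.counts[NMII][comp] += 1


def unbind_linker(state: NetworkState, lid: int) -> None:
    l = state.linkers.pop(lid)
    state.linker_sites.discard(l.site_a)
    state.linker_sites.discard(l.site_b)
    try:
        pa = state.site_position(l.site_a)
        comp = state.grid.index_of(pa)
    except KeyError:
        comp = (0, 0, 0)
    state.grid.counts[LINKER][comp] += 1


def next_site_toward_barbed(state: NetworkState, site: BindingSite) -> BindingSite | None:
    """The next discrete binding site toward the barbed end, or None."""
    f = state.filaments[site.fid]
    n_sites = len(state.params.binding_site_fractions)
    ci = f.cylinder_index(site.cid)
    if site.site_index + 1 < n_sites:
        return BindingSite(site.fid, site.cid, site.site_index + 1)
    if ci + 1 < len(f.cylinders):
        return BindingSite(site.fid, f.cylinders[ci + 1].cid, 0)
    return None


def motor_walk(state: NetworkState, mid: int, which: str) -> bool:
    """Advance one motor end one binding site toward the barbed end.

    Returns False (no-op) if there is no next site or it is occupied.
    The spring rest length keeps its binding-time value: moving the
    attachment site stretches the ensemble spring, which is how stepping
    generates contractile tension (throttled by the Hill force-velocity
    relation up to the ensemble stall force).
    """
    m = state.motors[mid]
    site = m.site_a if which == "a" else m.site_b
    nxt = next_site_toward_barbed(state, site)
    if nxt is None or nxt in state.motor_sites:
        return False
    state.motor_sites.discard(site)
    state.motor_sites.add(nxt)
    if which == "a":
        m.site_a = nxt
    else:
        m.site_b = nxt
    return True


# ---------------------------------------------------------------------------
# the event-driven engine

@dataclass
class ForceInputs:
    """Force factors for one chemistry window (from the last minimization)."""

    be_load: dict = field(default_factory=dict)       # fid -> pN
    pe_load: dict = field(default_factory=dict)
    motor_tension: dict = field(default_factory=dict)  # mid -> signed pN
    linker_tension: dict = field(default_factory=dict)
    # per-motor-end pulling force opposing the walk direction
    walk_load: dict = field(default_factory=dict)      # (mid, "a"|"b") -> pN


class ChemistryEngine:
    """Next-Reaction-Method driver for the full reaction network.

    Filament channels of the same kind are aggregated per compartment
    (superposition of exponential clocks is statistically exact): one
    channel carries the summed propensity and the firing filament is drawn
    proportionally to its weight. The queue is rebuilt from the current
    state at each chemistry-window boundary — exact by memorylessness —
    and updated incrementally within a window. Force factors are frozen
    per window.
    """

    def __init__(self, state: NetworkState, rng: np.random.Generator,
                 forces: ForceInputs | None = None,
                 event_log: list | None = None):
        self.state = state
        self.rng = rng
        self.forces = forces or ForceInputs()
        self.event_log = event_log
        self.n_events = 0
        self._comp_vol_L = (state.boundary.effective_volume_L
                            / state.grid.n_compartments)
        self.rebuild()

    # -- concentrations ------------------------------------------------
    def conc(self, species: str, comp: tuple) -> float:
        return self.state.grid.counts[species][comp] / (1e-6 * AVOGADRO * self._comp_vol_L)

    def conc_total(self, species: str) -> float:
        return self.state.grid.total(species) / (
            1e-6 * AVOGADRO * self.state.boundary.effective_volume_L)

    # -- per-entity rates ----------------------------------------------
    def _ratchet_weight(self, fid: int, end: str) -> float:
        chem = self.state.params.chem
        k0 = chem.k_on_BE if end == "BE" else chem.k_on_PE
        load = (self.forces.be_load if end == "BE" else self.forces.pe_load).get(fid, 0.0)
        return mechanochem.ratchet_poly_rate(k0, load,
                                             self.state.params.mechchem.F_poly0)

    def _motor_bind_propensity(self) -> float:
        if self._valid_pairs["motor"] <= 0:
            return 0.0
        return (self._next_heads * self.state.params.chem.k_on_head
                * self.state.grid.total(NMII))

    def _linker_bind_propensity(self) -> float:
        if self._valid_pairs["linker"] <= 0:
            return 0.0
        chem = self.state.params.chem
        return (chem.k_on_linker * self.conc_total(LINKER)
                * self._valid_pairs["linker"])

    def _motor_unbind_propensity(self, mid: int) -> float:
        m = self.state.motors[mid]
        mc = self.state.params.mechchem
        F = max(self.forces.motor_tension.get(mid, 0.0), 0.0)
        return mechanochem.catch_unbind_rate(
            self.state.params.chem.k_off_head, F, m.n_heads,
            beta=mc.beta, F_nmii_unbind=mc.F_nmii_unbind)

    def _linker_unbind_propensity(self, lid: int) -> float:
        mc = self.state.params.mechchem
        F = self.forces.linker_tension.get(lid, 0.0)
        return mechanochem.slip_unbind_rate(
            self.state.params.chem.k_off_linker, F, mc.F_linker_unbind)

    def _walk_propensity(self, mid: int, which: str) -> float:
        m = self.state.motors[mid]
        site = m.site_a if which == "a" else m.site_b
        try:
            nxt = next_site_toward_barbed(self.state, site)
        except KeyError:
            return 0.0
        if nxt is None:
            return 0.0
        mc = self.state.params.mechchem
        F = self.forces.walk_load.get((mid, which), 0.0)
        return mechanochem.hill_walk_rate(self.state.params.chem.k_walk0, F,
                                          m.n_heads, mc.F_stall, mc.xi)

    def _nuc_propensity(self, comp: tuple) -> float:
        g = self.state.grid.counts
        if g[G_ACTIN][comp] < 1:
            return 0.0
        return self.state.params.chem.k_nu * g[FORMIN][comp]

    def _hop_propensity(self, species: str, src: tuple) -> float:
        chem = self.state.params.chem
        rate = chem.D_diff / self.state.grid.edge ** 2
        return rate * self.state.grid.counts[species][src]

    # -- aggregate channel propensities --------------------------------
    def _agg_poly(self, comp: tuple, end: str) -> float:
        s = self._poly_w_sum[end].get(comp, 0.0)
        if s <= 0:
            return 0.0
        return s * self.conc(G_ACTIN, comp)

    def _agg_depoly(self, comp: tuple, end: str) -> float:
        chem = self.state.params.chem
        k = chem.k_off_BE if end == "BE" else chem.k_off_PE
        return k * len(self._eligible[end].get(comp, ()))

    def _agg_destroy(self, comp: tuple) -> float:
        return self.state.params.chem.k_destruction * len(self._two.get(comp, ()))

    def _agg_forminoff(self, comp: tuple) -> float:
        return self.state.params.chem.k_off_formin * len(self._fbe.get(comp, ()))

    # -- filament registry ---------------------------------------------
    def _register_filament(self, fid: int, update_queue: bool = True) -> None:
        state = self.state
        f = state.filaments[fid]
        cb = _tip_compartment(state, f, "BE")
        cp = _tip_compartment(state, f, "PE")
        self._fil_comp[fid] = (cb, cp)
        for end, comp in (("BE", cb), ("PE", cp)):
            w = self._ratchet_weight(fid, end)
            self._poly_w[end].setdefault(comp, {})[fid] = w
            self._poly_w_sum[end][comp] = self._poly_w_sum[end].get(comp, 0.0) + w
        n = f.n_monomers
        if n > 2:
            self._eligible["BE"].setdefault(cb, set()).add(fid)
            self._eligible["PE"].setdefault(cp, set()).add(fid)
        elif n == 2:
            self._two.setdefault(cb, set()).add(fid)
        if f.barbed_state == BARBED_FORMIN:
            self._fbe.setdefault(cb, set()).add(fid)
        if update_queue:
            self._touch_filament_channels(cb, cp)

    def _unregister_filament(self, fid: int, update_queue: bool = True) -> None:
        cb, cp = self._fil_comp.pop(fid)
        for end, comp in (("BE", cb), ("PE", cp)):
            w = self._poly_w[end][comp].pop(fid, 0.0)
            self._poly_w_sum[end][comp] -= w
            self._eligible[end].get(comp, set()).discard(fid)
        self._two.get(cb, set()).discard(fid)
        self._fbe.get(cb, set()).discard(fid)
        if update_queue:
            self._touch_filament_channels(cb, cp)

    def _touch_filament_channels(self, cb: tuple, cp: tuple) -> None:
        q = self.queue
        q.update(("polyBE", cb), self._agg_poly(cb, "BE"))
        q.update(("polyPE", cp), self._agg_poly(cp, "PE"))
        q.update(("depolyBE", cb), self._agg_depoly(cb, "BE"))
        q.update(("depolyPE", cp), self._agg_depoly(cp, "PE"))
        q.update(("destroy", cb), self._agg_destroy(cb))
        q.update(("forminoff", cb), self._agg_forminoff(cb))

    def _refresh_eligibility(self, fid: int) -> None:
        """Move a filament between the depoly/destroy registries after its
        monomer count changed; also handles the FBE registry."""
        state = self.state
        if fid not in state.filaments:
            return
        cb, cp = self._fil_comp[fid]
        f = state.filaments[fid]
        n = f.n_monomers
        if n > 2:
            self._eligible["BE"].setdefault(cb, set()).add(fid)
            self._eligible["PE"].setdefault(cp, set()).add(fid)
            self._two.get(cb, set()).discard(fid)
        elif n == 2:
            self._eligible["BE"].get(cb, set()).discard(fid)
            self._eligible["PE"].get(cp, set()).discard(fid)
            self._two.setdefault(cb, set()).add(fid)
        if f.barbed_state != BARBED_FORMIN:
            self._fbe.get(cb, set()).discard(fid)
        self._touch_filament_channels(cb, cp)

    # -- queue construction --------------------------------------------
    def rebuild(self, forces: ForceInputs | None = None) -> None:
        """Rebuild the whole queue from the current state (window boundary)."""
        if forces is not None:
            self.forces = forces
        state = self.state
        self.queue = NRMQueue(self.rng, time=state.time)
        q = self.queue
        self._next_heads = int(self.rng.integers(
            state.params.mechchem.n_heads_min,
            state.params.mechchem.n_heads_max + 1))
        # pair candidates and validity bookkeeping, as integer indices into
        # a per-window site table (skipped while a species is absent)
        self._sites = {}
        self._site_index = {}
        self._pairs = {}
        self._pair_blocked = {}
        self._site_pairs = {}
        self._valid_pairs = {}
        for sp, occupied, total in (
                ("motor", state.motor_sites,
                 state.grid.total(NMII) + len(state.motors)),
                ("linker", state.linker_sites,
                 state.grid.total(LINKER) + len(state.linkers))):
            if total > 0:
                sites, pos, pairs, _ = _pair_index_arrays(state, sp)
            else:
                sites, pairs = [], np.zeros((0, 2), dtype=np.int64)
            self._sites[sp] = sites
            self._site_index[sp] = {s: i for i, s in enumerate(sites)}
            self._pairs[sp] = pairs
            blocked = np.zeros(len(pairs), dtype=np.int64)
            site_pairs: dict = {}
            for k in range(len(pairs)):
                i, j = int(pairs[k, 0]), int(pairs[k, 1])
                site_pairs.setdefault(i, []).append(k)
                site_pairs.setdefault(j, []).append(k)
            self._site_pairs[sp] = site_pairs
            self._pair_blocked[sp] = blocked
            self._valid_pairs[sp] = int((blocked == 0).sum())
        # filament registries
        self._fil_comp = {}
        self._poly_w = {"BE": {}, "PE": {}}
        self._poly_w_sum = {"BE": {}, "PE": {}}
        self._eligible = {"BE": {}, "PE": {}}
        self._two = {}
        self._fbe = {}
        for fid in state.filaments:
            self._register_filament(fid, update_queue=False)
        grid = state.grid
        for idx in np.ndindex(grid.nx, grid.ny, grid.nz):
            q.add(("polyBE", idx), self._agg_poly(idx, "BE"))
            q.add(("polyPE", idx), self._agg_poly(idx, "PE"))
            q.add(("depolyBE", idx), self._agg_depoly(idx, "BE"))
            q.add(("depolyPE", idx), self._agg_depoly(idx, "PE"))
            q.add(("destroy", idx), self._agg_destroy(idx))
            q.add(("forminoff", idx), self._agg_forminoff(idx))
            q.add(("nuc", idx), self._nuc_propensity(idx))
        if grid.n_compartments > 1:
            for sp in (G_ACTIN, FORMIN, INTERMEDIATE, NMII, LINKER):
                for idx in np.ndindex(grid.nx, grid.ny, grid.nz):
                    for nb in grid.neighbors(idx):
                        q.add(("hop", sp, idx, nb), self._hop_propensity(sp, idx))
        for mid in state.motors:
            self._add_motor_channels(mid)
        for lid in state.linkers:
            q.add(("unbind_linker", lid), self._linker_unbind_propensity(lid))
        q.add(("bind_motor",), self._motor_bind_propensity())
        q.add(("bind_linker",), self._linker_bind_propensity())

    def _add_motor_channels(self, mid: int) -> None:
        q = self.queue
        q.add(("unbind_motor", mid), self._motor_unbind_propensity(mid))
        q.add(("walk", mid, "a"), self._walk_propensity(mid, "a"))
        q.add(("walk", mid, "b"), self._walk_propensity(mid, "b"))

    def _remove_motor_channels(self, mid: int) -> None:
        for cid in (("unbind_motor", mid), ("walk", mid, "a"), ("walk", mid, "b")):
            if cid in self.queue:
                self.queue.remove(cid)

    # -- occupancy bookkeeping ------------------------------------------
    def _occupy(self, sp: str, site: BindingSite) -> None:
        si = self._site_index[sp].get(site)
        if si is None:
            return
        blocked = self._pair_blocked[sp]
        for k in self._site_pairs[sp].get(si, ()):
            if blocked[k] == 0:
                self._valid_pairs[sp] -= 1
            blocked[k] += 1

    def _release(self, sp: str, site: BindingSite) -> None:
        si = self._site_index[sp].get(site)
        if si is None:
            return
        blocked = self._pair_blocked[sp]
        for k in self._site_pairs[sp].get(si, ()):
            blocked[k] -= 1
            if blocked[k] == 0:
                self._valid_pairs[sp] += 1

    def _site_alive(self, s: BindingSite) -> bool:
        f = self.state.filaments.get(s.fid)
        if f is None:
            return False
        try:
            f.cylinder_by_cid(s.cid)
        except KeyError:
            return False
        return True

    def _choose_pair(self, sp: str) -> BindingPairCandidate | None:
        """Uniform choice among currently valid pairs, with a liveness
        guard for candidates whose host cylinder vanished mid-window."""
        pairs = self._pairs[sp]
        blocked = self._pair_blocked[sp]
        sites = self._sites[sp]
        if self._valid_pairs[sp] <= 0 or len(pairs) == 0:
            return None

        def build(k):
            a, b = sites[int(pairs[k, 0])], sites[int(pairs[k, 1])]
            if not (self._site_alive(a) and self._site_alive(b)):
                return None
            pa = self.state.site_position(a)
            pb = self.state.site_position(b)
            return BindingPairCandidate(a, b, float(np.linalg.norm(pb - pa)))

        for _ in range(50):
            k = int(self.rng.integers(len(pairs)))
            if blocked[k] == 0:
                cand = build(k)
                if cand is not None:
                    return cand
        valid = np.nonzero(blocked == 0)[0]
        self.rng.shuffle(valid)
        for k in valid[:200]:
            cand = build(int(k))
            if cand is not None:
                return cand
        return None

    def _choose_weighted(self, weights: dict) -> int:
        total = sum(weights.values())
        u = self.rng.uniform(0.0, total)
        acc = 0.0
        last = None
        for fid, w in weights.items():
            acc += w
            last = fid
            if u <= acc:
                return fid
        return last

    def _choose_uniform(self, items: set) -> int:
        seq = sorted(items)
        return seq[int(self.rng.integers(len(seq)))]

    # -- propensity refresh after species-count changes -----------------
    def _g_changed(self, comp: tuple) -> None:
        q = self.queue
        q.update(("polyBE", comp), self._agg_poly(comp, "BE"))
        q.update(("polyPE", comp), self._agg_poly(comp, "PE"))
        q.update(("nuc", comp), self._nuc_propensity(comp))
        self._update_hops(G_ACTIN, comp)
        # fast nucleation step 2 fires as soon as G-actin is available
        g = self.state.grid.counts
        while g[INTERMEDIATE][comp] >= 1 and g[G_ACTIN][comp] >= 2:
            fid = nucleate_step2(self.state, comp, self.rng)
            if fid is None:
                break
            self._register_filament(fid)
            q.update(("polyBE", comp), self._agg_poly(comp, "BE"))
            q.update(("polyPE", comp), self._agg_poly(comp, "PE"))
            q.update(("nuc", comp), self._nuc_propensity(comp))

    def _update_hops(self, sp: str, comp: tuple) -> None:
        if self.state.grid.n_compartments == 1:
            return
        q = self.queue
        for nb in self.state.grid.neighbors(comp):
            cid = ("hop", sp, comp, nb)
            if cid in q:
                q.update(cid, self._hop_propensity(sp, comp))

    def _update_bind_channels(self) -> None:
        self.queue.update(("bind_motor",), self._motor_bind_propensity())
        self.queue.update(("bind_linker",), self._linker_bind_propensity())

    def _handle_released(self, released: list) -> None:
        for sp_kind, eid in released:
            if sp_kind == "motor":
                self._remove_motor_channels(eid)
            elif ("unbind_linker", eid) in self.queue:
                self.queue.remove(("unbind_linker", eid))
        if released:
            self._update_bind_channels()

    # -- the event loop --------------------------------------------------
    def advance_to(self, t_end: float) -> str:
        """Run events until t_end (exclusive); returns "ok" or "frozen"."""
        state = self.state
        q = self.queue
        while True:
            try:
                t, cid = q.peek()
            except ChemicallyFrozen:
                state.time = t_end
                return "frozen"
            if t > t_end:
                state.time = t_end
                q.time = t_end
                return "ok"
            q.pop()
            state.time = t
            self._fire(cid)
            self.n_events += 1
            if self.event_log is not None:
                self.event_log.append((t, cid))

    def _fire(self, cid: tuple) -> None:
        state = self.state
        q = self.queue
        kind = cid[0]
        if kind in ("polyBE", "polyPE"):
            end = kind[-2:]
            comp = cid[1]
            fid = self._choose_weighted(self._poly_w[end][comp])
            f = state.filaments[fid]
            if end == "BE":
                tip = f.barbed_cylinder.p_plus + MONOMER_SIZE * f.barbed_cylinder.axis
            else:
                tip = f.pointed_cylinder.p_minus - MONOMER_SIZE * f.pointed_cylinder.axis
            if state.boundary.distance_to_wall(tip) < 5.0:
                # hard-wall rejection: the stale within-window ratchet factor
                # cannot stop growth at the mechanical wall, so attempts that
                # would cross it are discarded
                pass
            else:
                polymerize(state, fid, end)
                self._refresh_eligibility(fid)
                self._g_changed(comp)
        elif kind in ("depolyBE", "depolyPE"):
            end = kind[-2:]
            comp = cid[1]
            fid = self._choose_uniform(self._eligible[end][comp])
            released = depolymerize(state, fid, end)
            self._handle_released(released)
            self._refresh_eligibility(fid)
            self._g_changed(comp)
        elif kind == "destroy":
            comp = cid[1]
            fid = self._choose_uniform(self._two[comp])
            released = destroy_filament(state, fid)
            self._handle_released(released)
            self._unregister_filament(fid)
            self._g_changed(comp)
            self._update_hops(FORMIN, comp)
            q.update(("nuc", comp), self._nuc_propensity(comp))
        elif kind == "forminoff":
            comp = cid[1]
            fid = self._choose_uniform(self._fbe[comp])
            formin_dissociate(state, fid)
            self._refresh_eligibility(fid)
            q.update(("nuc", comp), self._nuc_propensity(comp))
            self._update_hops(FORMIN, comp)
        elif kind == "nuc":
            comp = cid[1]
            nucleate_step1(state, comp)
            self._g_changed(comp)
            self._update_hops(FORMIN, comp)
            q.update(cid, self._nuc_propensity(comp))
        elif kind == "hop":
            _, sp, src, dst = cid
            diffusion_hop(state, sp, src, dst)
            self._update_hops(sp, src)
            self._update_hops(sp, dst)
            if sp == G_ACTIN:
                self._g_changed(src)
                self._g_changed(dst)
            elif sp == FORMIN:
                for c in (src, dst):
                    q.update(("nuc", c), self._nuc_propensity(c))
            elif sp == INTERMEDIATE:
                self._g_changed(dst)
            else:
                self._update_bind_channels()
        elif kind == "bind_motor":
            pair = self._choose_pair("motor")
            if pair is not None and state.grid.total(NMII) >= 1:
                mid = bind_motor(state, pair, self._next_heads, self.rng)
                self._occupy("motor", pair.site_a)
                self._occupy("motor", pair.site_b)
                self._add_motor_channels(mid)
                self._next_heads = int(self.rng.integers(
                    state.params.mechchem.n_heads_min,
                    state.params.mechchem.n_heads_max + 1))
            self._update_bind_channels()
        elif kind == "bind_linker":
            pair = self._choose_pair("linker")
            if pair is not None and state.grid.total(LINKER) >= 1:
                lid = bind_linker(state, pair, self.rng)
                self._occupy("linker", pair.site_a)
                self._occupy("linker", pair.site_b)
                q.add(("unbind_linker", lid),
                      self._linker_unbind_propensity(lid))
            self._update_bind_channels()
        elif kind == "unbind_motor":
            mid = cid[1]
            m = state.motors[mid]
            sa, sb = m.site_a, m.site_b
            unbind_motor(state, mid)
            self._release("motor", sa)
            self._release("motor", sb)
            self._remove_motor_channels(mid)
            self._update_bind_channels()
            return
        elif kind == "unbind_linker":
            lid = cid[1]
            l = state.linkers[lid]
            sa, sb = l.site_a, l.site_b
            unbind_linker(state, lid)
            self._release("linker", sa)
            self._release("linker", sb)
            q.remove(cid)
            self._update_bind_channels()
            return
        elif kind == "walk":
            _, mid, which = cid
            m = state.motors[mid]
            old = m.site_a if which == "a" else m.site_b
            moved = motor_walk(state, mid, which)
            if moved:
                new = m.site_a if which == "a" else m.site_b
                self._release("motor", old)
                self._occupy("motor", new)
                self._update_bind_channels()
                q.update(cid, self._walk_propensity(mid, which))
            # blocked attempts are discarded (rejection step)
        else:
            raise RuntimeError(f"unknown channel {cid!r}")
        if cid in q:
            q.redraw(cid)
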