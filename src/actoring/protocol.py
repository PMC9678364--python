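"""Chemistry–mechanics iteration and experiment scenarios.

One protocol cycle: (1) stochastic chemistry for one window, (2) energy
minimization of the polymeric phase, (3) force-dependent rate update,
(4) repeat. Scenarios reproduce the published perturbation protocols:
de-novo assembly with motor/linker addition at 300 s, Latrunculin-A-like
treadmilling inhibition at 800 s, and preformed-ring NMII perturbations
(Calyculin-A / Y-27632 analogues).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import Params, concentration_to_copies, MONOMER_SIZE
from .state import (NetworkState, BoundaryGeometry, CompartmentGrid, Filament,
                    Cylinder, Snapshot, Trajectory, validate_state,
                    G_ACTIN, FORMIN, NMII, LINKER, BARBED_FREE)
from .chemistry import (ChemistryEngine, ForceInputs, find_binding_pairs,
                        bind_motor, bind_linker, unbind_motor,
                        next_site_toward_barbed)
from .mechanics import minimize, MechanicalSystem


@dataclass
class ProtocolConfig:
    """Full specification of one simulation run."""

    params: Params = field(default_factory=Params)
    shape: str = "oblate"
    diameter: float = 4000.0          # mechanical (nm)
    height: float = 400.0             # mechanical (nm)
    conc_G: float = 40.0              # µM
    conc_formin: float = 0.1          # µM (100 nM)
    n_seed_filaments: int = 20
    seed_filament_monomers: int = 30
    dt_window: float = 0.010          # s
    total_time: float = 2000.0        # s
    snapshot_interval: float = 1.0    # s
    minimize_tol: float = 1.0         # pN
    minimize_max_iter: int = 5000
    schedule: list = field(default_factory=list)   # [(time, action tuple)]
    scaled_down: bool = False

    def __post_init__(self):
        if self.dt_window <= 0:
            raise ValueError("chemistry window must be positive")
        times = [t for t, _ in self.schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must strictly increase")

    def effective_boundary(self) -> BoundaryGeometry:
        return BoundaryGeometry(shape=self.shape, diameter=self.diameter,
                                height=self.height, a0=self.params.mech.a0)


def scaled_down_config(**overrides) -> ProtocolConfig:
    """Desk-scale configuration: 2 µm mechanical disk, well-mixed solution
    phase, 0.1 s chemistry window.

    Actin, NMII and crosslinker concentrations and all rate constants keep
    their full-scale values; the nucleator concentration is scaled up (and
    more seed filaments used) so that the mean filament length relative to
    the disk radius matches the full-scale regime (L/R ~ 0.3) — at raw
    concentrations a 2 µm disk holds a handful of radius-length filaments
    and every morphology degenerates to rim-hugging chords."""
    cfg = ProtocolConfig(diameter=2000.0, height=400.0, dt_window=0.1,
                         scaled_down=True, total_time=600.0,
                         minimize_tol=5.0, minimize_max_iter=400,
                         conc_formin=1.0, n_seed_filaments=60)
    cfg.params.compartment_edge = 4000.0      # single compartment
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# -- scenario presets -------------------------------------------------------

MOTOR_ADDITION_TIME = 300.0
LATA_TIME = 800.0
CONC_NMII = 0.06
CONC_LINKER = 4.0

# treadmilling arms: (k_on_BE, k_off_PE); slow is the in-vitro baseline,
# fast the three-fold boosted formin/cofilin condition
SLOW_TREADMILLING = (11.6, 0.8)
FAST_TREADMILLING = (34.8, 2.4)


def baseline_config(treadmilling: str = "slow", scaled: bool = True,
                    total_time: float = 600.0) -> ProtocolConfig:
    """De-novo assembly followed by NMII + alpha-actinin addition at 300 s.

    Slow treadmilling collapses into clusters, fast treadmilling forms a
    peripheral ring.
    """
    cfg = scaled_down_config(total_time=total_time) if scaled else ProtocolConfig(total_time=total_time)
    k_on, k_off = SLOW_TREADMILLING if treadmilling == "slow" else FAST_TREADMILLING
    cfg.params.chem.k_on_BE = k_on
    cfg.params.chem.k_off_PE = k_off
    cfg.schedule = [(MOTOR_ADDITION_TIME, ("add_species", NMII, CONC_NMII)),
                    (MOTOR_ADDITION_TIME + 1e-9, ("add_species", LINKER, CONC_LINKER))]
    return cfg


def calyculin_config(delta_nmii: float = 0.12, scaled: bool = True,
                     total_time: float = 300.0) -> ProtocolConfig:
    """NMII-enhancement analogue on a preformed ring.

    80 µM actin, 0.18 µM NMII baseline; extra NMII (default +0.12 µM) is
    added at t = 0 to drive whole-ring centripetal contraction. Build the
    starting state with :func:`init_preformed_ring` and pass it to
    :func:`run`.
    """
    cfg = scaled_down_config(total_time=total_time) if scaled         else ProtocolConfig(total_time=total_time)
    cfg.conc_G = 80.0
    cfg.conc_nmii = 0.18
    cfg.conc_linker = CONC_LINKER
    return apply_nmii_perturbation(cfg, delta_nmii, at_time=cfg.dt_window)


def y27632_config(delta_nmii: float = -0.04, scaled: bool = True,
                  total_time: float = 300.0) -> ProtocolConfig:
    """NMII-inhibition analogue: removes NMII (default 0.04 µM) from a
    preformed ring at t = 0, flattening the center-to-plateau profile."""
    return calyculin_config(delta_nmii=delta_nmii, scaled=scaled,
                            total_time=total_time)


def sphere_cortex_config(scaled: bool = True,
                         total_time: float = 600.0) -> ProtocolConfig:
    """Spherical confinement (cortex-like shell instead of a flat ring).

    Full scale uses a 4 µm sphere; the scaled variant a 2.4 µm sphere
    with the same desk-scale conventions as the oblate preset.
    """
    if scaled:
        cfg = scaled_down_config(total_time=total_time)
        cfg.shape = "sphere"
        cfg.diameter = 2400.0
    else:
        cfg = ProtocolConfig(shape="sphere", diameter=4000.0,
                             total_time=total_time)
    k_on, k_off = FAST_TREADMILLING
    cfg.params.chem.k_on_BE = k_on
    cfg.params.chem.k_off_PE = k_off
    cfg.schedule = [(MOTOR_ADDITION_TIME, ("add_species", NMII, CONC_NMII)),
                    (MOTOR_ADDITION_TIME + 1e-9,
                     ("add_species", LINKER, CONC_LINKER))]
    return cfg


def apply_latA(config: ProtocolConfig, level: str,
               at_time: float = LATA_TIME) -> ProtocolConfig:
    """Schedule Latrunculin-A-like treadmilling inhibition.

    weak:   k_on_BE=11.6 (µM·s)^-1, k_off_BE=2.1 s^-1, k_off_PE=2.4 s^-1
    strong: k_on_BE=3.48 (µM·s)^-1, k_off_BE=11.2 s^-1, k_off_PE=4.8 s^-1
    k_on_PE stays at 1.3 (µM·s)^-1 throughout. Idempotent.
    """
    if level == "weak":
        rates = {"k_on_BE": 11.6, "k_off_BE": 2.1, "k_off_PE": 2.4}
    elif level == "strong":
        rates = {"k_on_BE": 3.48, "k_off_BE": 11.2, "k_off_PE": 4.8}
    else:
        raise ValueError(f"unknown LatA level {level!r}")
    cfg = copy.deepcopy(config)
    actions = [(at_time + i * 1e-9, ("set_rate", k, v))
               for i, (k, v) in enumerate(sorted(rates.items()))]
    cfg.schedule = sorted(cfg.schedule + actions, key=lambda x: x[0])
    return cfg


def apply_nmii_perturbation(config: ProtocolConfig, delta_conc: float,
                            at_time: float = 0.0) -> ProtocolConfig:
    """Schedule addition (positive) or removal (negative) of NMII, in µM."""
    cfg = copy.deepcopy(config)
    cfg.schedule = sorted(cfg.schedule + [(at_time, ("add_nmii", delta_conc))],
                          key=lambda x: x[0])
    return cfg


# -- state initialization ---------------------------------------------------

def init_state(config: ProtocolConfig, rng: np.random.Generator) -> NetworkState:
    """De-novo initial state: diffusing G-actin/formin plus seed filaments."""
    boundary = config.effective_boundary()
    grid = CompartmentGrid(boundary, config.params.compartment_edge)
    state = NetworkState(boundary=boundary, grid=grid, params=config.params)
    V = boundary.effective_volume_L
    grid.add_uniform(G_ACTIN, concentration_to_copies(config.conc_G, V), rng)
    grid.add_uniform(FORMIN, concentration_to_copies(config.conc_formin, V), rng)
    for _ in range(config.n_seed_filaments):
        _place_seed_filament(state, config.seed_filament_monomers, rng)
    return state


def _place_seed_filament(state: NetworkState, n_monomers: int,
                         rng: np.random.Generator, max_tries: int = 200) -> int:
    from .chemistry import _random_orientation
    bnd = state.boundary
    length = n_monomers * MONOMER_SIZE
    for _ in range(max_tries):
        r = bnd.effective_radius * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        if bnd.shape == "oblate":
            z = rng.uniform(-bnd.effective_half_height, bnd.effective_half_height)
            center = np.array([r * math.cos(phi), r * math.sin(phi), z])
        else:
            v = rng.normal(size=3)
            center = v / np.linalg.norm(v) * r
        u = _random_orientation(bnd, rng)
        p0 = center - 0.5 * length * u
        p1 = center + 0.5 * length * u
        if bnd.inside_effective(p0) and bnd.inside_effective(p1):
            fid = state.new_fid()
            f = Filament(fid=fid, cylinders=[], barbed_state=BARBED_FREE)
            f.cylinders = [Cylinder(p_minus=p0, p_plus=p1,
                                    n_monomers=n_monomers, cid=f.new_cid())]
            f.L, f.R = 0, n_monomers
            state.filaments[fid] = f
            return fid
    raise RuntimeError("could not place seed filament inside boundary")


def init_preformed_ring(config: ProtocolConfig, rng: np.random.Generator,
                        ring_radius_frac: float = 0.85,
                        ring_width: float = 300.0,
                        filament_monomers: int = 100,
                        polymerized_fraction: float = 0.9,
                        bind_fraction: float = 1.0) -> NetworkState:
    """Construct a ring-like starting state instead of de-novo assembly.

    Filaments are laid out tangentially in an annulus at
    ``ring_radius_frac`` of the effective radius; the monomer budget
    matches the configured actin concentration, with
    ``polymerized_fraction`` of it in filaments. Motors and linkers are
    bound wherever their span windows permit.
    """
    if ring_width <= 0:
        raise ValueError("ring width must be positive")
    boundary = config.effective_boundary()
    grid = CompartmentGrid(boundary, config.params.compartment_edge)
    state = NetworkState(boundary=boundary, grid=grid, params=config.params)
    V = boundary.effective_volume_L
    total_actin = concentration_to_copies(config.conc_G, V)
    n_poly = int(polymerized_fraction * total_actin)
    grid.add_uniform(G_ACTIN, total_actin - n_poly, rng)
    grid.add_uniform(FORMIN, concentration_to_copies(config.conc_formin, V), rng)
    R = boundary.effective_radius
    zmax = boundary.effective_half_height if boundary.shape == "oblate" else 0.0
    placed = 0
    guard = 0
    while placed < n_poly and guard < 100000:
        guard += 1
        n_mono = min(filament_monomers, n_poly - placed)
        if n_mono < 3:
            break
        r = -1.0
        while not (0 < r < R - 5.0):
            r = ring_radius_frac * R + rng.normal(0.0, ring_width / 4.0)
        z = rng.uniform(-zmax, zmax) if zmax > 0 else 0.0
        phi0 = rng.uniform(0, 2 * math.pi)
        f = _tangential_filament(state, r, phi0, z, n_mono)
        if f is None:
            continue
        placed += n_mono
    if placed == 0:
        raise ValueError("infeasible ring packing: no filament placed")
    _bind_available(state, rng, config, bind_fraction)
    issues = validate_state(state)
    if issues:
        raise RuntimeError(f"preformed ring state invalid: {issues[:3]}")
    return state


def _tangential_filament(state: NetworkState, r: float, phi0: float, z: float,
                         n_monomers: int):
    """Polyline filament following the circle of radius r at height z."""
    fid = state.new_fid()
    f = Filament(fid=fid, cylinders=[], barbed_state=BARBED_FREE)
    remaining = n_monomers
    phi = phi0
    while remaining > 0:
        n = min(40, remaining)
        dphi = n * MONOMER_SIZE / r
        p0 = np.array([r * math.cos(phi), r * math.sin(phi), z])
        p1 = np.array([r * math.cos(phi + dphi), r * math.sin(phi + dphi), z])
        if not (state.boundary.inside_effective(p0)
                and state.boundary.inside_effective(p1)):
            return None
        f.cylinders.append(Cylinder(p_minus=p0, p_plus=p1, n_monomers=n,
                                    cid=f.new_cid()))
        phi += dphi
        remaining -= n
    # interior cylinders must be full: reorder so partial cylinder is last
    f.L, f.R = 0, n_monomers
    state.filaments[fid] = f
    return f


def _bind_available(state: NetworkState, rng: np.random.Generator,
                    config: ProtocolConfig, bind_fraction: float) -> None:
    V = state.boundary.effective_volume_L
    n_nmii = concentration_to_copies(getattr(config, "conc_nmii", CONC_NMII), V)
    n_link = concentration_to_copies(getattr(config, "conc_linker", CONC_LINKER), V)
    state.grid.add_uniform(NMII, n_nmii, rng)
    state.grid.add_uniform(LINKER, n_link, rng)
    for species, n_avail in (("motor", n_nmii), ("linker", n_link)):
        pairs = find_binding_pairs(state, species)
        rng.shuffle(pairs)
        occupied = state.motor_sites if species == "motor" else state.linker_sites
        n_bind = int(bind_fraction * n_avail)
        for pair in pairs:
            if n_bind <= 0:
                break
            if pair.site_a in occupied or pair.site_b in occupied:
                continue
            if species == "motor":
                if state.grid.total(NMII) < 1:
                    break
                n_heads = int(rng.integers(state.params.mechchem.n_heads_min,
                                           state.params.mechchem.n_heads_max + 1))
                bind_motor(state, pair, n_heads, rng)
            else:
                if state.grid.total(LINKER) < 1:
                    break
                bind_linker(state, pair, rng)
            n_bind -= 1


# -- force resolution for the rate laws ------------------------------------

def force_inputs_from(state: NetworkState, result) -> ForceInputs:
    """Translate a MinimizeResult into the per-channel force factors."""
    fi = ForceInputs(be_load=dict(result.forces.be_load),
                     pe_load=dict(result.forces.pe_load),
                     motor_tension=dict(result.forces.motor_tension),
                     linker_tension=dict(result.forces.linker_tension))
    for mid, m in state.motors.items():
        T = fi.motor_tension.get(mid, 0.0)
        for which, site, other in (("a", m.site_a, m.site_b),
                                   ("b", m.site_b, m.site_a)):
            try:
                cyl = state.filaments[site.fid].cylinder_by_cid(site.cid)
                step_dir = cyl.axis
                pa = state.site_position(site)
                pb = state.site_position(other)
            except KeyError:
                continue
            l = np.linalg.norm(pb - pa)
            if l == 0 or T <= 0:
                fi.walk_load[(mid, which)] = 0.0
                continue
            f_vec = T * (pb - pa) / l       # spring force on this end
            fi.walk_load[(mid, which)] = max(0.0, -float(np.dot(f_vec, step_dir)))
    return fi


# -- the run loop -----------------------------------------------------------

def run(config: ProtocolConfig, seed: int,
        state: NetworkState | None = None,
        chemistry_only: bool = False,
        progress: bool = False) -> Trajectory:
    """Execute the full chemistry–mechanics protocol.

    Bit-reproducible for a fixed seed. ``chemistry_only`` skips energy
    minimization (used for kinetics-focused runs without motors).
    """
    rng = np.random.default_rng(seed)
    if state is None:
        state = init_state(config, rng)
    traj = Trajectory(meta={"seed": seed, "config": "inline",
                            "dt_window": config.dt_window,
                            "scaled_down": config.scaled_down})
    schedule = sorted(config.schedule, key=lambda x: x[0])
    sched_i = 0
    engine = ChemistryEngine(state, rng)
    energy = {}
    if not chemistry_only:
        res = minimize(state, tol=config.minimize_tol,
                       max_iter=config.minimize_max_iter)
        energy = res.breakdown.as_dict()
        engine.rebuild(force_inputs_from(state, res))
    traj.append(Snapshot.capture(state, energy))
    next_snap = config.snapshot_interval
    t = state.time
    frozen_streak = 0
    while t < config.total_time - 1e-12:
        while sched_i < len(schedule) and schedule[sched_i][0] <= t + 1e-12:
            action = schedule[sched_i][1]
            if action[0] == "stop":
                traj.meta["status"] = "stopped"
                return traj
            _apply_action(state, engine, action, rng)
            engine.rebuild()
            sched_i += 1
        t_next = min(t + config.dt_window, config.total_time)
        status = engine.advance_to(t_next)
        t = t_next
        if chemistry_only:
            if status == "frozen":
                frozen_streak += 1
                if frozen_streak > 2:
                    traj.meta["status"] = "frozen"
                    break
            else:
                frozen_streak = 0
        else:
            res = minimize(state, tol=config.minimize_tol,
                           max_iter=config.minimize_max_iter)
            energy = res.breakdown.as_dict()
            engine.rebuild(force_inputs_from(state, res))
            if status == "frozen" and res.converged and res.n_iter == 0:
                frozen_streak += 1
                if frozen_streak > 2:
                    traj.meta["status"] = "frozen"
                    break
            else:
                frozen_streak = 0
        if t + 1e-9 >= next_snap:
            traj.append(Snapshot.capture(state, energy))
            next_snap += config.snapshot_interval
        if progress and int(t) % 50 == 0 and abs(t - round(t)) < config.dt_window / 2:
            print(f"  t={t:8.1f} s  filaments={len(state.filaments)} "
                  f"events={engine.n_events}", flush=True)
    traj.meta.setdefault("status", "completed")
    traj.meta["n_events"] = engine.n_events
    return traj


def _apply_action(state: NetworkState, engine: ChemistryEngine, action: tuple,
                  rng: np.random.Generator) -> None:
    kind = action[0]
    if kind == "add_species":
        _, species, conc = action
        n = concentration_to_copies(conc, state.boundary.effective_volume_L)
        state.grid.add_uniform(species, n, rng)
    elif kind == "set_rate":
        _, name, value = action
        if not hasattr(state.params.chem, name):
            raise KeyError(f"unknown rate {name!r}")
        setattr(state.params.chem, name, value)
    elif kind == "add_nmii":
        _, delta_conc = action
        n = concentration_to_copies(abs(delta_conc),
                                    state.boundary.effective_volume_L)
        if delta_conc >= 0:
            state.grid.add_uniform(NMII, n, rng)
        else:
            remove_nmii(state, n, rng)
    else:
        raise ValueError(f"unknown schedule action {action!r}")


def remove_nmii(state: NetworkState, n: int, rng: np.random.Generator) -> None:
    """Remove n NMII copies: diffusing pool first, then forced unbinding."""
    if n > state.total_nmii():
        raise ValueError("cannot remove more NMII than the system contains")
    flat = state.grid.counts[NMII]
    take = min(n, int(flat.sum()))
    removed = 0
    while removed < take:
        idx = np.unravel_index(int(rng.integers(flat.size)), flat.shape)
        if flat[idx] > 0:
            flat[idx] -= 1
            removed += 1
    n -= take
    mids = list(state.motors)
    rng.shuffle(mids)
    for mid in mids[:n]:
        unbind_motor(state, mid)
        # forced unbinding returned a copy to the pool; remove it again
        flat2 = state.grid.counts[NMII]
        nz = np.argwhere(flat2 > 0)
        idx = tuple(nz[int(rng.integers(len(nz)))])
        flat2[idx] -= 1
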