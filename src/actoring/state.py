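"""Network state: geometry, filaments, bound species, solution compartments.

The polymeric phase holds semiflexible filaments discretized as chains of
cylinders (2.7 nm to 108 nm equilibrium length, i.e. 1-40 monomers), with
motor ensembles (NMII mini-filaments) and passive crosslinkers
(alpha-actinin) as two-point harmonic springs attached to filament binding
sites. The solution phase is a compartment grid of integer copy numbers
for diffusing species.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .params import Params, MONOMER_SIZE, MAX_MONOMERS_PER_CYLINDER

# Diffusing species names
G_ACTIN = "G"
FORMIN = "formin"
INTERMEDIATE = "intermediate"   # formin-G-actin nucleation intermediate
NMII = "NMII"
LINKER = "linker"
SPECIES = (G_ACTIN, FORMIN, INTERMEDIATE, NMII, LINKER)

BARBED_FREE = "BE"
BARBED_FORMIN = "FBE"
POINTED = "PE"


@dataclass
class BoundaryGeometry:
    """Confining volume: thin oblate disk or sphere.

    The *mechanical* surface (where the repulsion is anchored) is given by
    ``diameter`` and ``height``; the *effective* boundary that actually
    confines the network sits ``a0`` inside it (e.g. mechanical height
    400 nm with a0 = 100 nm gives an effective height of 200 nm).
    """

    shape: str = "oblate"           # "oblate" | "sphere"
    diameter: float = 4000.0        # mechanical diameter (nm)
    height: float = 400.0           # mechanical height (nm, oblate only)
    a0: float = 100.0

    def __post_init__(self):
        if self.shape not in ("oblate", "sphere"):
            raise ValueError(f"unknown boundary shape {self.shape!r}")
        if self.effective_radius <= 0:
            raise ValueError("effective radius must be positive")
        if self.shape == "oblate" and self.effective_half_height <= 0:
            raise ValueError("effective half-height must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def effective_radius(self) -> float:
        return self.radius - self.a0

    @property
    def effective_half_height(self) -> float:
        return self.height / 2.0 - self.a0

    @property
    def effective_volume_L(self) -> float:
        """Volume enclosed by the effective boundary, in litres."""
        if self.shape == "sphere":
            v_nm3 = 4.0 / 3.0 * np.pi * self.effective_radius ** 3
        else:
            v_nm3 = np.pi * self.effective_radius ** 2 * 2 * self.effective_half_height
        return v_nm3 * 1e-24

    def distance_to_wall(self, points: np.ndarray) -> np.ndarray:
        """Distance from point(s) to the mechanical surface (positive inside)."""
        p = np.atleast_2d(points)
        if self.shape == "sphere":
            d = self.radius - np.linalg.norm(p, axis=1)
        else:
            r_xy = np.hypot(p[:, 0], p[:, 1])
            d_side = self.radius - r_xy
            d_cap = self.height / 2.0 - np.abs(p[:, 2])
            d = np.minimum(d_side, d_cap)
        return d if points.ndim == 2 else d[0]

    def inside_effective(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d = self.distance_to_wall(p)
        out = d >= self.a0
        return out if np.ndim(points) == 2 else out[0]


@dataclass
class Cylinder:
    """One filament element: a straight segment carrying 1-40 monomers."""

    p_minus: np.ndarray             # pointed-side endpoint (nm)
    p_plus: np.ndarray              # barbed-side endpoint (nm)
    n_monomers: int
    cid: int = 0                    # stable id within its filament

    @property
    def eq_length(self) -> float:
        return MONOMER_SIZE * self.n_monomers

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_plus - self.p_minus))

    @property
    def axis(self) -> np.ndarray:
        v = self.p_plus - self.p_minus
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero-length cylinder has no axis")
        return v / n

    def point_at(self, frac: float) -> np.ndarray:
        return (1.0 - frac) * self.p_minus + frac * self.p_plus


@dataclass
class Filament:
    """Ordered chain of cylinders, pointed end first.

    Monomers are indexed by a lab-frame interval [L, R): pointed-end removal
    advances L, barbed-end addition advances R. This gives exact subunit
    identity for FRAP-like turnover bookkeeping without per-monomer objects.
    """

    fid: int
    cylinders: list                 # list[Cylinder], pointed -> barbed
    barbed_state: str = BARBED_FREE
    pointed_state: str = POINTED
    L: int = 0
    R: int = 0
    # cumulative end-event counters
    be_added: int = 0
    be_removed: int = 0
    pe_added: int = 0
    pe_removed: int = 0
    _next_cid: int = 0

    @property
    def n_monomers(self) -> int:
        return sum(c.n_monomers for c in self.cylinders)

    @property
    def barbed_cylinder(self) -> Cylinder:
        return self.cylinders[-1]

    @property
    def pointed_cylinder(self) -> Cylinder:
        return self.cylinders[0]

    def new_cid(self) -> int:
        self._next_cid += 1
        return self._next_cid - 1

    def cylinder_by_cid(self, cid: int) -> Cylinder:
        for c in self.cylinders:
            if c.cid == cid:
                return c
        raise KeyError(f"filament {self.fid} has no cylinder {cid}")

    def cylinder_index(self, cid: int) -> int:
        for i, c in enumerate(self.cylinders):
            if c.cid == cid:
                return i
        raise KeyError(f"filament {self.fid} has no cylinder {cid}")

    def monomer_positions(self) -> np.ndarray:
        """(n_monomers, 3) array of monomer centers along the chain."""
        out = []
        for c in self.cylinders:
            t = (np.arange(c.n_monomers) + 0.5) / c.n_monomers
            out.append(c.p_minus[None, :] + t[:, None] * (c.p_plus - c.p_minus)[None, :])
        return np.concatenate(out, axis=0)


@dataclass(frozen=True)
class BindingSite:
    """Reference to a discrete binding site on a filament cylinder."""

    fid: int
    cid: int
    site_index: int                 # index into Params.binding_site_fractions


@dataclass
class MotorEnsemble:
    """NMII mini-filament: 15-30 heads acting as one two-ended spring."""

    mid: int
    n_heads: int
    site_a: BindingSite
    site_b: BindingSite
    eq_length: float                # reset on every walking step (nm)


@dataclass
class Linker:
    """Alpha-actinin crosslinker: passive two-ended spring with slip bond."""

    lid: int
    site_a: BindingSite
    site_b: BindingSite
    eq_length: float


class CompartmentGrid:
    """Per-compartment integer copy numbers for the diffusing species.

    A uniform grid of cubic compartments of the given edge length covering
    the bounding box of the confinement; compartments are identified by
    flat indices. The well-mixed limit is a 1x1x1 grid.
    """

    def __init__(self, boundary: BoundaryGeometry, edge: float):
        if edge <= 0:
            raise ValueError("compartment edge must be positive")
        self.edge = float(edge)
        self.boundary = boundary
        R = boundary.radius
        if boundary.shape == "sphere":
            half_z = R
        else:
            half_z = boundary.height / 2.0
        self.nx = max(1, int(np.ceil(2 * R / edge)))
        self.ny = max(1, int(np.ceil(2 * R / edge)))
        self.nz = max(1, int(np.ceil(2 * half_z / edge)))
        self.origin = np.array([-self.nx * edge / 2.0,
                                -self.ny * edge / 2.0,
                                -self.nz * edge / 2.0])
        self.counts = {s: np.zeros((self.nx, self.ny, self.nz), dtype=np.int64)
                       for s in SPECIES}

    @property
    def n_compartments(self) -> int:
        return self.nx * self.ny * self.nz

    def index_of(self, point: np.ndarray) -> tuple:
        ijk = np.floor((np.asarray(point) - self.origin) / self.edge).astype(int)
        ijk = np.clip(ijk, 0, [self.nx - 1, self.ny - 1, self.nz - 1])
        return tuple(ijk)

    def center_of(self, idx: tuple) -> np.ndarray:
        return self.origin + (np.asarray(idx) + 0.5) * self.edge

    def neighbors(self, idx: tuple) -> list:
        i, j, k = idx
        out = []
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < self.nx and 0 <= nj < self.ny and 0 <= nk < self.nz:
                out.append((ni, nj, nk))
        return out

    def total(self, species: str) -> int:
        return int(self.counts[species].sum())

    def hop(self, species: str, src: tuple, dst: tuple) -> None:
        """Move one molecule between adjacent compartments."""
        if self.counts[species][src] < 1:
            raise ValueError(f"hop from empty compartment {src} ({species})")
        if sum(abs(a - b) for a, b in zip(src, dst)) != 1:
            raise ValueError("compartments are not adjacent")
        self.counts[species][src] -= 1
        self.counts[species][dst] += 1

    def add_uniform(self, species: str, n: int, rng: np.random.Generator) -> None:
        """Distribute n copies uniformly over compartments (multinomial)."""
        if self.n_compartments == 1:
            self.counts[species][0, 0, 0] += n
            return
        flat = rng.multinomial(n, np.full(self.n_compartments, 1.0 / self.n_compartments))
        self.counts[species] += flat.reshape(self.nx, self.ny, self.nz)

    def copy(self) -> "CompartmentGrid":
        g = CompartmentGrid.__new__(CompartmentGrid)
        g.edge = self.edge
        g.boundary = self.boundary
        g.nx, g.ny, g.nz = self.nx, self.ny, self.nz
        g.origin = self.origin.copy()
        g.counts = {s: a.copy() for s, a in self.counts.items()}
        return g


@dataclass
class NetworkState:
    """Full mutable simulation state (both phases)."""

    boundary: BoundaryGeometry
    grid: CompartmentGrid
    params: Params
    time: float = 0.0
    filaments: dict = field(default_factory=dict)     # fid -> Filament
    motors: dict = field(default_factory=dict)        # mid -> MotorEnsemble
    linkers: dict = field(default_factory=dict)       # lid -> Linker
    motor_sites: set = field(default_factory=set)     # occupied BindingSites
    linker_sites: set = field(default_factory=set)
    _next_fid: int = 0
    _next_mid: int = 0
    _next_lid: int = 0
    # system-wide cumulative end-event counters (survive filament destruction)
    tot_be_added: int = 0
    tot_be_removed: int = 0
    tot_pe_added: int = 0
    tot_pe_removed: int = 0

    def new_fid(self) -> int:
        self._next_fid += 1
        return self._next_fid - 1

    def new_mid(self) -> int:
        self._next_mid += 1
        return self._next_mid - 1

    def new_lid(self) -> int:
        self._next_lid += 1
        return self._next_lid - 1

    # ---- bookkeeping queries ----------------------------------------
    def total_actin(self) -> int:
        """G-actin + polymerized monomers + monomers inside intermediates."""
        return (self.grid.total(G_ACTIN)
                + sum(f.n_monomers for f in self.filaments.values())
                + self.grid.total(INTERMEDIATE))

    def total_formin(self) -> int:
        bound = sum(1 for f in self.filaments.values()
                    if f.barbed_state == BARBED_FORMIN)
        return self.grid.total(FORMIN) + self.grid.total(INTERMEDIATE) + bound

    def total_nmii(self) -> int:
        return self.grid.total(NMII) + len(self.motors)

    def total_linker(self) -> int:
        return self.grid.total(LINKER) + len(self.linkers)

    def site_position(self, site: BindingSite) -> np.ndarray:
        cyl = self.filaments[site.fid].cylinder_by_cid(site.cid)
        frac = self.params.binding_site_fractions[site.site_index]
        return cyl.point_at(frac)

    def monomer_positions(self) -> np.ndarray:
        if not self.filaments:
            return np.zeros((0, 3))
        return np.concatenate([f.monomer_positions()
                               for f in self.filaments.values()], axis=0)


def validate_state(state: NetworkState) -> list[str]:
    """Check every structural invariant; return list of violations (empty = ok)."""
    v: list[str] = []
    for fid, f in state.filaments.items():
        if not f.cylinders:
            v.append(f"filament {fid}: no cylinders")
            continue
        if f.n_monomers < 2:
            v.append(f"filament {fid}: fewer than 2 monomers")
        if f.R - f.L != f.n_monomers:
            v.append(f"filament {fid}: monomer interval [L,R) inconsistent with cylinders")
        for i, c in enumerate(f.cylinders):
            if not (1 <= c.n_monomers <= MAX_MONOMERS_PER_CYLINDER):
                v.append(f"filament {fid} cylinder {c.cid}: n_monomers={c.n_monomers} out of range")
            if abs(c.eq_length - MONOMER_SIZE * c.n_monomers) > 1e-12:
                v.append(f"filament {fid} cylinder {c.cid}: eq_length mismatch")
            if c.length <= 0:
                v.append(f"filament {fid} cylinder {c.cid}: non-positive length")
            interior = 0 < i < len(f.cylinders) - 1
            if interior and c.n_monomers != MAX_MONOMERS_PER_CYLINDER:
                v.append(f"filament {fid} cylinder {c.cid}: interior cylinder not full")
        for a, b in zip(f.cylinders[:-1], f.cylinders[1:]):
            if not np.allclose(a.p_plus, b.p_minus, atol=1e-6):
                v.append(f"filament {fid}: cylinders {a.cid},{b.cid} do not share an endpoint")
        if f.barbed_state not in (BARBED_FREE, BARBED_FORMIN):
            v.append(f"filament {fid}: bad barbed_state {f.barbed_state}")
    for mid, m in state.motors.items():
        if m.site_a.fid == m.site_b.fid:
            v.append(f"motor {mid}: both sites on filament {m.site_a.fid}")
        if not (15 <= m.n_heads <= 30):
            v.append(f"motor {mid}: n_heads={m.n_heads} outside [15,30]")
        for s in (m.site_a, m.site_b):
            if s.fid not in state.filaments:
                v.append(f"motor {mid}: dangling site on filament {s.fid}")
    for lid, l in state.linkers.items():
        if l.site_a.fid == l.site_b.fid:
            v.append(f"linker {lid}: both sites on filament {l.site_a.fid}")
        for s in (l.site_a, l.site_b):
            if s.fid not in state.filaments:
                v.append(f"linker {lid}: dangling site on filament {s.fid}")
    for sp, arr in state.grid.counts.items():
        if (arr < 0).any():
            v.append(f"grid: negative copy number for {sp}")
    return v


@dataclass
class Snapshot:
    """Frozen copy of the network at one time point, plus derived records."""

    time: float
    boundary: BoundaryGeometry
    filaments: dict                    # fid -> Filament (deep copies)
    motors: dict
    linkers: dict
    grid_counts: dict                  # species -> ndarray
    energy: dict = field(default_factory=dict)   # term name -> pN·nm
    tot_be_added: int = 0
    tot_be_removed: int = 0
    tot_pe_added: int = 0
    tot_pe_removed: int = 0

    @classmethod
    def capture(cls, state: NetworkState, energy: dict | None = None) -> "Snapshot":
        return cls(
            time=state.time,
            boundary=state.boundary,
            filaments=copy.deepcopy(state.filaments),
            motors=copy.deepcopy(state.motors),
            linkers=copy.deepcopy(state.linkers),
            grid_counts={s: a.copy() for s, a in state.grid.counts.items()},
            energy=dict(energy or {}),
            tot_be_added=state.tot_be_added,
            tot_be_removed=state.tot_be_removed,
            tot_pe_added=state.tot_pe_added,
            tot_pe_removed=state.tot_pe_removed,
        )

    @property
    def n_filaments(self) -> int:
        return len(self.filaments)

    def monomer_positions(self) -> np.ndarray:
        if not self.filaments:
            return np.zeros((0, 3))
        return np.concatenate([f.monomer_positions()
                               for f in self.filaments.values()], axis=0)

    def mean_filament_length_nm(self) -> float:
        if not self.filaments:
            return 0.0
        return MONOMER_SIZE * np.mean([f.n_monomers for f in self.filaments.values()])


@dataclass
class Trajectory:
    """Time-ordered sequence of snapshots with run metadata."""

    snapshots: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def append(self, snap: Snapshot) -> None:
        if self.snapshots and snap.time <= self.snapshots[-1].time:
            raise ValueError("snapshot times must strictly increase")
        self.snapshots.append(snap)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]
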