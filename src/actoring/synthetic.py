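"""Synthetic ground-truth fixtures for the analysis and image pipelines.

Generates (a) network snapshots with prescribed morphology — uniform disk,
peripheral ring, compact clusters — (b) TIRF-like rendered intensity
images with Gaussian PSF, Poisson photon noise and optional bleaching, and
(c) synthetic end-event logs and turnover trajectories with known rates.
Everything is deterministic under a fixed seed; fixtures make no attempt
at mechanical plausibility (no energy minimization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .params import MONOMER_SIZE
from .state import (BoundaryGeometry, Cylinder, Filament, Snapshot,
                    Trajectory, BARBED_FREE)
from .imaging import IntensityImage


@dataclass
class MorphologySpec:
    kind: str                        # "uniform" | "ring" | "clusters"
    boundary: BoundaryGeometry = field(
        default_factory=lambda: BoundaryGeometry(diameter=4000.0, height=400.0))
    total_monomers: int = 20000
    filament_monomers: int = 40      # one full cylinder by default
    ring_radius_frac: float = 0.9
    ring_width_nm: float = 50.0
    n_clusters: int = 1
    cluster_centers_frac: list | None = None   # [(x_frac, y_frac), ...]
    cluster_sigma_nm: float = 150.0

    def analytic_r_median(self) -> float:
        """Construction target for the normalized radial median."""
        if self.kind == "uniform":
            return 1.0 / math.sqrt(2.0)
        if self.kind == "ring":
            return self.ring_radius_frac
        centers = self.cluster_centers_frac or [(0.0, 0.0)]
        return float(np.median([math.hypot(x, y) for x, y in centers]))


@dataclass
class RenderSpec:
    pixel_size_nm: float = 50.0
    psf_sigma_nm: float = 100.0
    photons_per_monomer: float = 20.0
    background: float = 2.0
    bleach_factor: float = 1.0       # per-frame multiplicative decay
    noise: bool = True

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        for name in ("psf_sigma_nm", "photons_per_monomer", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_snapshot(spec: MorphologySpec, rng: np.random.Generator | int) -> Snapshot:
    """Build a snapshot of straight filaments realizing the morphology.

    Ring filaments are oriented tangentially; uniform and cluster
    filaments isotropically in-plane. All monomers lie inside the
    effective boundary.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    bnd = spec.boundary
    R = bnd.effective_radius
    zmax = bnd.effective_half_height if bnd.shape == "oblate" else 0.6 * R
    filaments = {}
    placed = 0
    fid = 0
    length = spec.filament_monomers * MONOMER_SIZE
    guard = 0
    while placed < spec.total_monomers:
        guard += 1
        if guard > 100 * (spec.total_monomers // spec.filament_monomers + 10):
            raise RuntimeError("infeasible morphology packing")
        center, u = _sample_center_orientation(spec, R, zmax, rng)
        # keep the center and retry orientations: rejecting the center as
        # well would deplete monomer density near the rim and bias the
        # realized radial median inward
        ok = False
        for _ in range(64):
            p0 = center - 0.5 * length * u
            p1 = center + 0.5 * length * u
            if bnd.inside_effective(p0) and bnd.inside_effective(p1):
                ok = True
                break
            u = _reorient(spec, center, rng)
        if not ok:
            continue
        f = Filament(fid=fid, cylinders=[], barbed_state=BARBED_FREE)
        f.cylinders = [Cylinder(p_minus=p0, p_plus=p1,
                                n_monomers=spec.filament_monomers, cid=0)]
        f._next_cid = 1
        f.L, f.R = 0, spec.filament_monomers
        filaments[fid] = f
        fid += 1
        placed += spec.filament_monomers
    return Snapshot(time=0.0, boundary=bnd, filaments=filaments,
                    motors={}, linkers={}, grid_counts={})


def _sample_center_orientation(spec, R, zmax, rng):
    z = rng.uniform(-zmax, zmax)
    if spec.kind == "uniform":
        r = R * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        center = np.array([r * math.cos(phi), r * math.sin(phi), z])
        u = _inplane_orientation(rng)
    elif spec.kind == "ring":
        r = rng.normal(spec.ring_radius_frac * R, spec.ring_width_nm)
        r = min(max(r, 0.0), R - 1.0)
        phi = rng.uniform(0, 2 * math.pi)
        center = np.array([r * math.cos(phi), r * math.sin(phi), z])
        u = np.array([-math.sin(phi), math.cos(phi), 0.0])   # tangential
    elif spec.kind == "clusters":
        centers = spec.cluster_centers_frac or [(0.0, 0.0)] * spec.n_clusters
        cx, cy = centers[int(rng.integers(len(centers)))]
        off = rng.normal(0.0, spec.cluster_sigma_nm, size=2)
        center = np.array([cx * R + off[0], cy * R + off[1], z])
        u = _inplane_orientation(rng)
    else:
        raise ValueError(f"unknown morphology {spec.kind!r}")
    return center, u


def _reorient(spec, center, rng):
    if spec.kind == "ring":
        r = math.hypot(center[0], center[1])
        if r > 0:
            return np.array([-center[1] / r, center[0] / r, 0.0])
    return _inplane_orientation(rng)


def _inplane_orientation(rng):
    phi = rng.uniform(0, 2 * math.pi)
    return np.array([math.cos(phi), math.sin(phi), 0.0])


def render_image(snapshot: Snapshot, spec: RenderSpec,
                 rng: np.random.Generator | int = 0) -> IntensityImage:
    """Render a snapshot as a TIRF-like 2D intensity image.

    Monomer positions are binned to pixels, convolved with a Gaussian PSF,
    scaled to photons, bleached by the per-frame factor, and Poisson
    sampled over the constant background. Expected integrated signal is
    proportional to the total polymerized actin.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    bnd = snapshot.boundary
    R = bnd.effective_radius
    extent = 1.25 * R
    n_px = int(np.ceil(2 * extent / spec.pixel_size_nm))
    edges = np.linspace(-extent, extent, n_px + 1)
    pos = snapshot.monomer_positions()
    H = np.histogram2d(pos[:, 1], pos[:, 0], bins=(edges, edges))[0] if len(pos) \
        else np.zeros((n_px, n_px))
    sigma_px = spec.psf_sigma_nm / spec.pixel_size_nm
    blurred = ndimage.gaussian_filter(H, sigma_px, mode="constant")
    expected = blurred * spec.photons_per_monomer * spec.bleach_factor + spec.background
    data = rng.poisson(expected).astype(float) if spec.noise else expected
    return IntensityImage(data=data, pixel_size_nm=spec.pixel_size_nm)


def render_series(snapshot: Snapshot, spec: RenderSpec, n_frames: int,
                  bleach_per_frame: float,
                  rng: np.random.Generator | int = 0) -> list:
    """Multi-frame render of a fixed morphology with exponential bleaching."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    frames = []
    for k in range(n_frames):
        fspec = RenderSpec(pixel_size_nm=spec.pixel_size_nm,
                           psf_sigma_nm=spec.psf_sigma_nm,
                           photons_per_monomer=spec.photons_per_monomer,
                           background=spec.background,
                           bleach_factor=bleach_per_frame ** k,
                           noise=spec.noise)
        frames.append(render_image(snapshot, fspec, rng))
    return frames


# -- synthetic kinetics fixtures -------------------------------------------

def make_event_log(be_rate: float, pe_rate: float, n_filaments: int,
                   t_max: float, dt: float,
                   rng: np.random.Generator | int = 0) -> Trajectory:
    """Trajectory whose cumulative end counters follow Poisson streams with
    the given per-filament rates (monomers/s); filament count and length
    are held constant so the kinetic steady state spans the whole log."""
    if be_rate < 0 or pe_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    bnd = BoundaryGeometry(diameter=4000.0, height=400.0)
    filaments = {}
    for i in range(n_filaments):
        f = Filament(fid=i, cylinders=[
            Cylinder(p_minus=np.array([0.0, 0.0, 0.0]),
                     p_plus=np.array([108.0, 0.0, 0.0]), n_monomers=40, cid=0)])
        f.L, f.R = 0, 40
        filaments[i] = f
    traj = Trajectory(meta={"synthetic": True})
    be_cum = 0
    pe_cum = 0
    t = 0.0
    snap0 = Snapshot(time=t, boundary=bnd, filaments=filaments, motors={},
                     linkers={}, grid_counts={})
    traj.append(snap0)
    while t < t_max - 1e-9:
        t += dt
        be_cum += rng.poisson(be_rate * n_filaments * dt)
        pe_cum += rng.poisson(pe_rate * n_filaments * dt)
        traj.append(Snapshot(time=t, boundary=bnd, filaments=filaments,
                             motors={}, linkers={}, grid_counts={},
                             tot_be_added=be_cum, tot_pe_removed=pe_cum))
    return traj


def make_turnover_trajectory(k_turnover: float, n_filaments: int,
                             t_max: float, dt: float,
                             rng: np.random.Generator | int = 0,
                             quantile_spacing: bool = False) -> Trajectory:
    """Trajectory with exponential subunit turnover at rate ``k_turnover``:
    each (2-monomer) filament is replaced at an exponential time, so the
    originally labeled fraction decays as exp(-k t); t_1/2 = ln2/k.

    With ``quantile_spacing`` the replacement times are the exact
    exponential quantiles instead of random draws, making the decay curve
    noise-free (useful to check analytic values exactly)."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if k_turnover <= 0:
        death = np.full(n_filaments, np.inf)
    elif quantile_spacing:
        q = (np.arange(n_filaments) + 0.5) / n_filaments
        death = -np.log(1.0 - q) / k_turnover
    else:
        death = rng.exponential(1.0 / k_turnover, size=n_filaments)
    bnd = BoundaryGeometry(diameter=4000.0, height=400.0)

    def filaments_at(t):
        out = {}
        for i in range(n_filaments):
            f = Filament(fid=i, cylinders=[
                Cylinder(p_minus=np.array([0.0, 0.0, 0.0]),
                         p_plus=np.array([5.4, 0.0, 0.0]), n_monomers=2, cid=0)])
            if death[i] <= t:
                # replaced: same id namespace retired, new filament id
                out[n_filaments + i] = f
                f.fid = n_filaments + i
            else:
                out[i] = f
            f.L, f.R = 0, 2
        return out

    traj = Trajectory(meta={"synthetic": True})
    t = 0.0
    while t < t_max + 1e-9:
        traj.append(Snapshot(time=t if t > 0 else 0.0, boundary=bnd,
                             filaments=filaments_at(t), motors={}, linkers={},
                             grid_counts={}))
        t += dt
    return traj
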