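"""Quantitative readouts of network morphology and kinetics.

- radial filament density profile and its normalized median R_median
  (≈ 1/√2 for a uniform disk, → 1 for peripheral rings, → 0 for central
  clusters)
- remodeling rate: slope of the linear part of the R_median time series
- treadmilling rate ⟨r_TM⟩: net barbed-end elongation per filament per
  second at kinetic steady state (equal to pointed-end depletion there)
- FRAP-like turnover halftime from labeled-monomer bookkeeping
- grid-based cluster detection (100 nm bins, 160 µM threshold, ≥ 4 bins)
  and local actin concentration
- filament orientation relative to the boundary tangent
- mechanical energy series U_Mech
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .params import AVOGADRO, MONOMER_SIZE
from .state import Snapshot, Trajectory

CLUSTER_BIN_NM = 100.0
CLUSTER_THRESHOLD_UM = 160.0
CLUSTER_MIN_BINS = 4


# -- radial statistics ------------------------------------------------------

@dataclass
class RadialProfile:
    r: np.ndarray            # bin centers, fraction of effective radius
    rho: np.ndarray          # area-normalized density, integrates to 1
    r_median: float


def radial_density(snapshot: Snapshot, n_bins: int = 50) -> RadialProfile:
    """Area-normalized radial distribution of polymerized actin.

    Each monomer is assigned to a radial bin by its in-plane distance from
    the volume center; the profile is divided by annulus area and then
    normalized so that sum(rho * dr) = 1.
    """
    pos = snapshot.monomer_positions()
    if len(pos) == 0:
        raise ValueError("empty snapshot")
    R = snapshot.boundary.effective_radius
    r = np.hypot(pos[:, 0], pos[:, 1]) / R
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(r, 0, 1 - 1e-12), bins=edges)
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    rho = counts / area
    dr = edges[1] - edges[0]
    norm = rho.sum() * dr
    if norm > 0:
        rho = rho / norm
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(r=centers, rho=rho, r_median=r_median(snapshot))


def r_median(snapshot: Snapshot) -> float:
    """Normalized median of monomer radial positions (0..1)."""
    pos = snapshot.monomer_positions()
    if len(pos) == 0:
        raise ValueError("empty snapshot")
    R = snapshot.boundary.effective_radius
    return float(np.median(np.hypot(pos[:, 0], pos[:, 1])) / R)


def r_median_series(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    times, values = [], []
    for s in traj.snapshots:
        if s.n_filaments == 0:
            continue
        times.append(s.time)
        values.append(r_median(s))
    return np.array(times), np.array(values)


# -- remodeling rate --------------------------------------------------------

def remodeling_rate(times: np.ndarray, series: np.ndarray,
                    window_start: float = 0.0, min_window: float = 50.0,
                    r2_min: float = 0.9, resid_frac: float = 0.01) -> float:
    """Slope (s^-1) of the longest linear segment of an R_median series.

    The linear part is the longest contiguous window after ``window_start``
    whose least-squares fit reaches R^2 >= ``r2_min`` and whose RMS
    residual stays below ``resid_frac`` of the series range (minimum
    length ``min_window`` seconds); the residual criterion stops a
    ramp-then-plateau series from being swallowed by one global fit.
    Falls back to the global fit when no window qualifies. Positive slope
    = centrifugal remodeling.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    sel = times >= window_start
    t = times[sel]
    y = series[sel]
    if len(t) < 10:
        raise ValueError("series too short for remodeling-rate estimation")
    # O(1) windowed regression via prefix sums
    c1 = np.concatenate([[0], np.cumsum(t)])
    c2 = np.concatenate([[0], np.cumsum(t * t)])
    cy = np.concatenate([[0], np.cumsum(y)])
    cyy = np.concatenate([[0], np.cumsum(y * y)])
    cty = np.concatenate([[0], np.cumsum(t * y)])

    y_range = max(float(y.max() - y.min()), 1e-12)
    # noise-aware residual threshold: allow the larger of resid_frac*range
    # and ~1.5 sigma of the point noise (robustly estimated from second
    # differences, whose std is sigma*sqrt(6) for iid noise)
    if len(y) > 4:
        d2 = np.diff(y, 2)
        sigma_hat = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)
    else:
        sigma_hat = 0.0
    resid_cap = max(resid_frac * y_range, 1.5 * sigma_hat)

    def fit(i, j):                      # window [i, j)
        n = j - i
        st = c1[j] - c1[i]
        stt = c2[j] - c2[i]
        sy = cy[j] - cy[i]
        syy = cyy[j] - cyy[i]
        sty = cty[j] - cty[i]
        denom = n * stt - st * st
        if denom <= 0:
            return 0.0, 1.0, 0.0
        slope = (n * sty - st * sy) / denom
        ss_tot = syy - sy * sy / n
        if ss_tot <= 1e-18:
            return slope, 1.0, 0.0      # constant series: perfect fit
        ss_res = max(ss_tot - slope * (sty - st * sy / n), 0.0)
        return slope, 1.0 - ss_res / ss_tot, math.sqrt(ss_res / n)

    best = None                          # (length, -start, slope)
    n = len(t)
    for i in range(n):
        for j in range(n, i + 1, -1):
            if t[j - 1] - t[i] < min_window:
                break
            if best is not None and t[j - 1] - t[i] <= best[0]:
                break
            slope, r2, rms = fit(i, j)
            if r2 >= r2_min and rms <= resid_cap:
                length = t[j - 1] - t[i]
                cand = (length, -t[i], slope)
                if best is None or cand[:2] > best[:2]:
                    best = cand
                break                    # longer j already failed or recorded
    if best is None:
        # fall back to the global fit over the whole window
        slope, _, _ = fit(0, n)
        return float(slope)
    return float(best[2])


# -- treadmilling -----------------------------------------------------------

@dataclass
class TreadmillingReport:
    rtm: float                       # net BE elongation rate (monomers/s/filament)
    pe_rate: float                   # net PE shortening rate
    times: np.ndarray = field(default=None, repr=False)
    mean_length_nm: np.ndarray = field(default=None, repr=False)
    steady_state_onset: float = 0.0

    @property
    def balanced(self) -> bool:
        scale = max(abs(self.rtm), abs(self.pe_rate), 1e-12)
        return abs(self.rtm - self.pe_rate) / scale < 0.1


def steady_state_onset(times: np.ndarray, mean_length: np.ndarray,
                       window: float = 100.0, tol: float = 0.02) -> float:
    """First time where the rolling-mean filament length changes by less
    than ``tol`` per ``window`` seconds."""
    times = np.asarray(times)
    for i, t in enumerate(times):
        prev = (times >= t - window) & (times < t)
        nxt = (times >= t) & (times < t + window)
        if prev.sum() < 2 or nxt.sum() < 2:
            continue
        m0 = mean_length[prev].mean()
        m1 = mean_length[nxt].mean()
        if m0 > 0 and abs(m1 - m0) / m0 < tol:
            return float(t)
    return float(times[-1])


def treadmilling_rate(traj: Trajectory, t_start: float | None = None) -> TreadmillingReport:
    """⟨r_TM⟩ from the cumulative end-event counters of a trajectory.

    rtm = (net BE additions over [t_start, end]) / (duration × mean
    filament count); the pointed-end depletion rate is computed the same
    way. ``t_start`` defaults to the detected steady-state onset.
    """
    snaps = traj.snapshots
    if len(snaps) < 2:
        raise ValueError("trajectory too short")
    times = traj.times
    mean_len = np.array([s.mean_filament_length_nm() for s in snaps])
    onset = steady_state_onset(times, mean_len)
    if t_start is None:
        t_start = onset
    sel = [s for s in snaps if s.time >= t_start]
    if len(sel) < 2:
        raise ValueError("no snapshots after t_start")
    s0, s1 = sel[0], sel[-1]
    duration = s1.time - s0.time
    if duration <= 0:
        raise ValueError("zero-duration analysis window")
    mean_count = np.mean([s.n_filaments for s in sel])
    if mean_count == 0:
        raise ValueError("no filaments in analysis window")
    be_net = (s1.tot_be_added - s1.tot_be_removed) - (s0.tot_be_added - s0.tot_be_removed)
    pe_net = (s1.tot_pe_removed - s1.tot_pe_added) - (s0.tot_pe_removed - s0.tot_pe_added)
    return TreadmillingReport(rtm=be_net / duration / mean_count,
                              pe_rate=pe_net / duration / mean_count,
                              times=times, mean_length_nm=mean_len,
                              steady_state_onset=onset)


# -- FRAP-like turnover -----------------------------------------------------

@dataclass
class TurnoverResult:
    t_half: float                    # s (nan if censored)
    censored: bool
    times: np.ndarray = field(default=None, repr=False)
    labeled_fraction: np.ndarray = field(default=None, repr=False)


def turnover_halftime(traj: Trajectory, label_time: float) -> TurnoverResult:
    """Photobleaching-mimicking turnover: label all polymerized monomers at
    ``label_time`` and follow the fraction still polymerized.

    Subunit identity comes from each filament's monomer interval [L, R):
    the labeled block of filament f is its interval at label time, and the
    surviving labeled count is the overlap of the current interval with it.
    t_1/2 is the first time the fraction reaches 0.5 (linear interpolation);
    censored if it never does within the trajectory.
    """
    snaps = [s for s in traj.snapshots if s.time >= label_time]
    if not snaps:
        raise ValueError("label_time beyond trajectory")
    ref = snaps[0]
    labels = {fid: (f.L, f.R) for fid, f in ref.filaments.items()}
    total0 = sum(R - L for L, R in labels.values())
    if total0 == 0:
        raise ValueError("no polymerized actin at label time")
    times, frac = [], []
    for s in snaps:
        alive = 0
        for fid, (L0, R0) in labels.items():
            f = s.filaments.get(fid)
            if f is None:
                continue
            alive += max(0, min(f.R, R0) - max(f.L, L0))
        times.append(s.time)
        frac.append(alive / total0)
    times = np.array(times)
    frac = np.array(frac)
    below = np.nonzero(frac <= 0.5)[0]
    if len(below) == 0:
        return TurnoverResult(t_half=float("nan"), censored=True,
                              times=times, labeled_fraction=frac)
    i = below[0]
    if i == 0:
        t_half = times[0] - label_time
    else:
        f0, f1 = frac[i - 1], frac[i]
        t0, t1 = times[i - 1], times[i]
        t_half = t0 + (0.5 - f0) / (f1 - f0) * (t1 - t0) - label_time
    return TurnoverResult(t_half=float(t_half), censored=False,
                          times=times, labeled_fraction=frac)


# -- cluster detection ------------------------------------------------------

@dataclass
class ClusterSet:
    clusters: list                   # each: dict(bins=list[(i,j)], mean_conc=µM)
    bin_conc: np.ndarray             # full 2D concentration map (µM)
    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray

    def __len__(self):
        return len(self.clusters)


def detect_clusters(snapshot: Snapshot, bin_nm: float = CLUSTER_BIN_NM,
                    threshold_uM: float = CLUSTER_THRESHOLD_UM,
                    min_bins: int = CLUSTER_MIN_BINS,
                    connectivity: int = 4) -> ClusterSet:
    """Density-based cluster detection on a 100 nm × 100 nm grid.

    Per-bin F-actin concentration (monomers / bin volume, in µM, using the
    effective network height), thresholded at 160 µM; connected components
    (4-connectivity by default) smaller than 4 bins are ignored.
    """
    pos = snapshot.monomer_positions()
    bnd = snapshot.boundary
    R = bnd.effective_radius
    n = int(np.ceil(2 * R / bin_nm))
    edges = np.linspace(-R, R, n + 1)
    H = np.histogram2d(pos[:, 0], pos[:, 1], bins=(edges, edges))[0] if len(pos) else np.zeros((n, n))
    height = (2 * bnd.effective_half_height if bnd.shape == "oblate"
              else 2 * bnd.effective_radius)
    v_bin_L = bin_nm * bin_nm * height * 1e-24
    conc = H / (v_bin_L * AVOGADRO * 1e-6)
    mask = conc >= threshold_uM
    structure = (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]) if connectivity == 4
                 else np.ones((3, 3)))
    lab, n_lab = ndimage.label(mask, structure=structure)
    clusters = []
    for k in range(1, n_lab + 1):
        bins = np.argwhere(lab == k)
        if len(bins) < min_bins:
            continue
        vals = conc[lab == k]
        clusters.append({"bins": [tuple(b) for b in bins],
                         "mean_conc": float(vals.mean()),
                         "n_bins": len(bins)})
    return ClusterSet(clusters=clusters, bin_conc=conc,
                      bin_edges_x=edges, bin_edges_y=edges)


def local_concentration(clusters: ClusterSet) -> float:
    """Mean F-actin concentration over all member bins of all clusters (µM)."""
    if len(clusters) == 0:
        raise ValueError("no clusters detected")
    vals = []
    for c in clusters.clusters:
        vals.extend(clusters.bin_conc[i, j] for i, j in c["bins"])
    return float(np.mean(vals))


# -- orientation ------------------------------------------------------------

def orientation_distribution(snapshot: Snapshot, n_bins: int = 18):
    """Histogram of the angle between each cylinder axis and the local
    boundary tangent (azimuthal direction) at its midpoint, folded to
    [0°, 90°]. Returns (bin_centers_deg, counts)."""
    angles = []
    for f in snapshot.filaments.values():
        for c in f.cylinders:
            mid = 0.5 * (c.p_minus + c.p_plus)
            r = np.hypot(mid[0], mid[1])
            if r < 1e-9:
                continue
            tangent = np.array([-mid[1], mid[0], 0.0]) / r
            axis = c.axis
            cosang = abs(float(np.dot(axis, tangent)))
            angles.append(np.degrees(np.arccos(np.clip(cosang, 0, 1))))
    counts, edges = np.histogram(angles, bins=n_bins, range=(0.0, 90.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


# -- mechanical energy ------------------------------------------------------

def mechanical_energy_series(traj: Trajectory,
                             steady_window: float = 500.0):
    """U_Mech per snapshot (bending + stretching of filaments, motors and
    linkers; boundary term excluded) and its mean over the final
    ``steady_window`` seconds. Returns (times, u_mech, window_mean)."""
    times, u = [], []
    for s in traj.snapshots:
        e = s.energy
        if not e:
            raise ValueError(f"snapshot at t={s.time} lacks an energy breakdown")
        if "U_mech" in e:
            u.append(e["U_mech"])
        else:
            u.append(e["U_fil_bend"] + e["U_fil_str"]
                     + e["U_motor_str"] + e["U_linker_str"])
        times.append(s.time)
    times = np.array(times)
    u = np.array(u)
    sel = times >= times[-1] - steady_window
    return times, u, float(u[sel].mean())
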