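"""Potential energy terms, analytic gradients, and FIRE energy minimization.

Mechanics is quasi-static: after every chemistry window the network relaxes
to a local energy minimum (time-scale separation between elastic relaxation
and chemical events), and the relaxed forces feed the force-dependent rate
laws. Terms:

- cylinder axial stretching        U = 1/2 K_str (l - l0)^2
- inter-cylinder bending           U = K_bend (1 - cos(theta - theta0))
- excluded volume (optional)       U = K_vol * double line integral of 1/r^4
- motor/linker harmonic springs    U = 1/2 K_eff (l - l0)^2
- boundary repulsion               U = eps * exp(-(d - a0)/lambda)

All energies are in pN·nm, forces in pN, coordinates in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss

from .params import Params, MechParams
from .state import (BoundaryGeometry, Cylinder, Filament, NetworkState,
                    MotorEnsemble, Linker)

EXCLUDED_VOLUME_CAP = 1.0e12     # pN·nm, cap for intersecting segments
EXCLUDED_VOLUME_CUTOFF = 100.0   # nm, neighbor cutoff for the pair sum


# ---------------------------------------------------------------------------
# scalar per-element energies (reference API; the minimizer uses the
# vectorized internals below)

def stretch_energy(cylinder: Cylinder, K_fil_str: float) -> float:
    """Axial stretching energy of one cylinder."""
    return 0.5 * K_fil_str * (cylinder.length - cylinder.eq_length) ** 2


def bend_energy(cyl_a: Cylinder, cyl_b: Cylinder, K_fil_bend: float,
                theta0: float = 0.0) -> float:
    """Bending energy of two consecutive cylinders sharing a vertex."""
    u = cyl_a.p_plus - cyl_a.p_minus
    v = cyl_b.p_plus - cyl_b.p_minus
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("bend angle undefined for zero-length cylinder")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(c)
    return K_fil_bend * (1.0 - np.cos(theta - theta0))


def spring_energy(element: MotorEnsemble | Linker, state: NetworkState) -> float:
    """Harmonic stretching energy of a bound motor ensemble or crosslinker."""
    pa = state.site_position(element.site_a)
    pb = state.site_position(element.site_b)
    l = float(np.linalg.norm(pb - pa))
    if isinstance(element, MotorEnsemble):
        K = state.params.mech.K_nmii_str_per_head * element.n_heads
    else:
        K = state.params.mech.K_linker_str
    return 0.5 * K * (l - element.eq_length) ** 2


def boundary_energy(point: np.ndarray, geometry: BoundaryGeometry,
                    mech: MechParams) -> float:
    """Exponential boundary repulsion at one sample point."""
    d = float(geometry.distance_to_wall(np.asarray(point, dtype=float)))
    return mech.eps_boundary * np.exp(-(d - mech.a0) / mech.lambda_screen)


def excluded_volume_energy(cyl_i: Cylinder, cyl_j: Cylinder, K_vol: float,
                           n_quad: int = 16) -> float:
    """Steric repulsion between two cylinders: K_vol * ∬ dl_i dl_j / r^4.

    Evaluated with tensor-product Gauss-Legendre quadrature. Intersecting
    or touching segments make the integral divergent; those are capped at
    a large finite value with a warning.
    """
    nodes, wts = leggauss(n_quad)
    s = 0.5 * (nodes + 1.0)          # map to [0,1]
    w = 0.5 * wts
    a0, a1 = cyl_i.p_minus, cyl_i.p_plus
    b0, b1 = cyl_j.p_minus, cyl_j.p_plus
    La, Lb = cyl_i.length, cyl_j.length
    xi = a0[None, :] + s[:, None] * (a1 - a0)[None, :]
    yj = b0[None, :] + s[:, None] * (b1 - b0)[None, :]
    diff = xi[:, None, :] - yj[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    if _segment_distance(a0, a1, b0, b1) < 1e-9:
        warnings.warn("intersecting cylinders: excluded-volume energy capped")
        return EXCLUDED_VOLUME_CAP
    S = np.einsum("i,j,ij->", w, w, 1.0 / r2 ** 2)
    U = K_vol * La * Lb * S
    if U > EXCLUDED_VOLUME_CAP:
        warnings.warn("near-intersecting cylinders: excluded-volume energy capped")
        return EXCLUDED_VOLUME_CAP
    return float(U)


def _segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 3D segments."""
    u = a1 - a0
    v = b1 - b0
    w0 = a0 - b0
    a = np.dot(u, u)
    b = np.dot(u, v)
    c = np.dot(v, v)
    d = np.dot(u, w0)
    e = np.dot(v, w0)
    denom = a * c - b * b
    if denom > 1e-14:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-14 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for clamped t
    if a > 1e-14:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(a0 + s * u - (b0 + t * v)))


# ---------------------------------------------------------------------------
# energy breakdown / force field containers

@dataclass
class EnergyBreakdown:
    U_fil_str: float = 0.0
    U_fil_bend: float = 0.0
    U_vol: float = 0.0
    U_motor_str: float = 0.0
    U_linker_str: float = 0.0
    U_boundary: float = 0.0

    @property
    def U_total(self) -> float:
        return (self.U_fil_str + self.U_fil_bend + self.U_vol
                + self.U_motor_str + self.U_linker_str + self.U_boundary)

    @property
    def U_mech(self) -> float:
        """Reported mechanical energy: bending + stretching of filaments,
        motors and linkers (boundary and steric terms excluded)."""
        return (self.U_fil_bend + self.U_fil_str
                + self.U_motor_str + self.U_linker_str)

    def as_dict(self) -> dict:
        return {"U_fil_str": self.U_fil_str, "U_fil_bend": self.U_fil_bend,
                "U_vol": self.U_vol, "U_motor_str": self.U_motor_str,
                "U_linker_str": self.U_linker_str, "U_boundary": self.U_boundary,
                "U_total": self.U_total, "U_mech": self.U_mech}


@dataclass
class ForceField:
    """Post-minimization forces fed to the mechanochemical rate laws."""

    vertex_forces: np.ndarray                      # (n_vertices, 3), pN
    be_load: dict = field(default_factory=dict)    # fid -> compressive load (pN)
    pe_load: dict = field(default_factory=dict)
    motor_tension: dict = field(default_factory=dict)   # mid -> signed F (pN)
    linker_tension: dict = field(default_factory=dict)  # lid -> signed F (pN)



def _scatter_add(g: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """g[idx] += vals via bincount (faster than ufunc.at for our sizes)."""
    n = g.shape[0]
    for k in range(3):
        g[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)



try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:                  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True, fastmath=True)
def _core_energy_grad(x, cyl_i0, cyl_i1, cyl_eq, K_str, K_bend,
                      sp_i0, sp_i1, sp_f, sp_j0, sp_j1, sp_g, sp_K, sp_l0,
                      sp_is_motor, bnd_i0, bnd_i1, bnd_t,
                      is_sphere, R, halfH, eps, lam, a0, exp_max):
    """Fused loop kernel for stretch + bend + springs + boundary.

    Returns (U6, grad) with U6 = [str, bend, 0, motor, linker, boundary].
    """
    n = x.shape[0]
    g = np.zeros((n, 3))
    U = np.zeros(6)
    m = cyl_i0.shape[0]
    for k in range(m):
        i = cyl_i0[k]
        j = cyl_i1[k]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        l = math.sqrt(dx * dx + dy * dy + dz * dz)
        dl = l - cyl_eq[k]
        U[0] += 0.5 * K_str * dl * dl
        if l > 0:
            c = K_str * dl / l
            g[j, 0] += c * dx; g[j, 1] += c * dy; g[j, 2] += c * dz
            g[i, 0] -= c * dx; g[i, 1] -= c * dy; g[i, 2] -= c * dz
    # bending over consecutive cylinder pairs (shared interior vertices)
    for k in range(m - 1):
        if cyl_i1[k] != cyl_i0[k + 1]:
            continue
        i0 = cyl_i0[k]; i1 = cyl_i1[k]; i2 = cyl_i1[k + 1]
        ux = x[i1, 0] - x[i0, 0]; uy = x[i1, 1] - x[i0, 1]; uz = x[i1, 2] - x[i0, 2]
        vx = x[i2, 0] - x[i1, 0]; vy = x[i2, 1] - x[i1, 1]; vz = x[i2, 2] - x[i1, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        if nu == 0 or nv == 0:
            continue
        inv = 1.0 / (nu * nv)
        c = (ux * vx + uy * vy + uz * vz) * inv
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        U[1] += K_bend * (1.0 - c)
        cu = c / (nu * nu)
        cv = c / (nv * nv)
        gux = -K_bend * (vx * inv - cu * ux)
        guy = -K_bend * (vy * inv - cu * uy)
        guz = -K_bend * (vz * inv - cu * uz)
        gvx = -K_bend * (ux * inv - cv * vx)
        gvy = -K_bend * (uy * inv - cv * vy)
        gvz = -K_bend * (uz * inv - cv * vz)
        g[i0, 0] -= gux; g[i0, 1] -= guy; g[i0, 2] -= guz
        g[i1, 0] += gux - gvx; g[i1, 1] += guy - gvy; g[i1, 2] += guz - gvz
        g[i2, 0] += gvx; g[i2, 1] += gvy; g[i2, 2] += gvz
    for k in range(sp_K.shape[0]):
        f = sp_f[k]; gr = sp_g[k]
        ax = (1 - f) * x[sp_i0[k], 0] + f * x[sp_i1[k], 0]
        ay = (1 - f) * x[sp_i0[k], 1] + f * x[sp_i1[k], 1]
        az = (1 - f) * x[sp_i0[k], 2] + f * x[sp_i1[k], 2]
        bx = (1 - gr) * x[sp_j0[k], 0] + gr * x[sp_j1[k], 0]
        by = (1 - gr) * x[sp_j0[k], 1] + gr * x[sp_j1[k], 1]
        bz = (1 - gr) * x[sp_j0[k], 2] + gr * x[sp_j1[k], 2]
        dx = bx - ax; dy = by - ay; dz = bz - az
        l = math.sqrt(dx * dx + dy * dy + dz * dz)
        dl = l - sp_l0[k]
        e = 0.5 * sp_K[k] * dl * dl
        if sp_is_motor[k]:
            U[3] += e
        else:
            U[4] += e
        if l > 0:
            c = sp_K[k] * dl / l
            fx = c * dx; fy = c * dy; fz = c * dz
            g[sp_j0[k], 0] += (1 - gr) * fx; g[sp_j0[k], 1] += (1 - gr) * fy; g[sp_j0[k], 2] += (1 - gr) * fz
            g[sp_j1[k], 0] += gr * fx; g[sp_j1[k], 1] += gr * fy; g[sp_j1[k], 2] += gr * fz
            g[sp_i0[k], 0] -= (1 - f) * fx; g[sp_i0[k], 1] -= (1 - f) * fy; g[sp_i0[k], 2] -= (1 - f) * fz
            g[sp_i1[k], 0] -= f * fx; g[sp_i1[k], 1] -= f * fy; g[sp_i1[k], 2] -= f * fz
    for k in range(bnd_i0.shape[0]):
        t = bnd_t[k]
        px = (1 - t) * x[bnd_i0[k], 0] + t * x[bnd_i1[k], 0]
        py = (1 - t) * x[bnd_i0[k], 1] + t * x[bnd_i1[k], 1]
        pz = (1 - t) * x[bnd_i0[k], 2] + t * x[bnd_i1[k], 2]
        ddx = 0.0; ddy = 0.0; ddz = 0.0
        if is_sphere:
            r = math.sqrt(px * px + py * py + pz * pz)
            d = R - r
            if r > 0:
                ddx = -px / r; ddy = -py / r; ddz = -pz / r
        else:
            rxy = math.sqrt(px * px + py * py)
            d_side = R - rxy
            d_cap = halfH - abs(pz)
            if d_side < d_cap:
                d = d_side
                if rxy > 0:
                    ddx = -px / rxy; ddy = -py / rxy
            else:
                d = d_cap
                ddz = -1.0 if pz > 0 else 1.0
        z = -(d - a0) / lam
        if z > exp_max:
            z = exp_max
        Ub = eps * math.exp(z)
        U[5] += Ub
        c = -Ub / lam
        g[bnd_i0[k], 0] += (1 - t) * c * ddx
        g[bnd_i0[k], 1] += (1 - t) * c * ddy
        g[bnd_i0[k], 2] += (1 - t) * c * ddz
        g[bnd_i1[k], 0] += t * c * ddx
        g[bnd_i1[k], 1] += t * c * ddy
        g[bnd_i1[k], 2] += t * c * ddz
    return U, g


# ---------------------------------------------------------------------------
# assembled vectorized system

class MechanicalSystem:
    """Flattened view of the polymeric phase for vectorized energy/gradient.

    Topology (vertex indices, spring attachments) is frozen at construction;
    only coordinates vary during minimization.
    """

    def __init__(self, state: NetworkState):
        self.state = state
        p = state.params
        self.mech = p.mech
        self.boundary = state.boundary
        verts = []
        self.fil_base: dict = {}
        cyl_pairs = []
        cyl_eq = []
        bend_triplets = []
        for fid in sorted(state.filaments):
            f = state.filaments[fid]
            base = len(verts)
            self.fil_base[fid] = base
            verts.append(f.cylinders[0].p_minus)
            for i, c in enumerate(f.cylinders):
                verts.append(c.p_plus)
                cyl_pairs.append((base + i, base + i + 1))
                cyl_eq.append(c.eq_length)
            for i in range(len(f.cylinders) - 1):
                bend_triplets.append((base + i, base + i + 1, base + i + 2))
        self.x0 = np.array(verts, dtype=float) if verts else np.zeros((0, 3))
        self.cyl_pairs = np.array(cyl_pairs, dtype=np.int64).reshape(-1, 2)
        self.cyl_eq = np.array(cyl_eq, dtype=float)
        self.bend_triplets = np.array(bend_triplets, dtype=np.int64).reshape(-1, 3)

        # springs: endpoints as (iv_minus, iv_plus, frac)
        sp_i0, sp_i1, sp_frac = [], [], []
        sp_j0, sp_j1, sp_gfrac = [], [], []
        sp_K, sp_l0 = [], []
        self.spring_ids = []
        fractions = p.binding_site_fractions

        def endpoint(site):
            f = state.filaments[site.fid]
            ci = f.cylinder_index(site.cid)
            base = self.fil_base[site.fid]
            return base + ci, base + ci + 1, fractions[site.site_index]

        for mid in sorted(state.motors):
            m = state.motors[mid]
            i0, i1, fr = endpoint(m.site_a)
            j0, j1, gr = endpoint(m.site_b)
            sp_i0.append(i0); sp_i1.append(i1); sp_frac.append(fr)
            sp_j0.append(j0); sp_j1.append(j1); sp_gfrac.append(gr)
            sp_K.append(self.mech.K_nmii_str_per_head * m.n_heads)
            sp_l0.append(m.eq_length)
            self.spring_ids.append(("motor", mid))
        for lid in sorted(state.linkers):
            l = state.linkers[lid]
            i0, i1, fr = endpoint(l.site_a)
            j0, j1, gr = endpoint(l.site_b)
            sp_i0.append(i0); sp_i1.append(i1); sp_frac.append(fr)
            sp_j0.append(j0); sp_j1.append(j1); sp_gfrac.append(gr)
            sp_K.append(self.mech.K_linker_str)
            sp_l0.append(l.eq_length)
            self.spring_ids.append(("linker", lid))
        self.sp_i0 = np.array(sp_i0, dtype=np.int64)
        self.sp_i1 = np.array(sp_i1, dtype=np.int64)
        self.sp_frac = np.array(sp_frac, dtype=float)
        self.sp_j0 = np.array(sp_j0, dtype=np.int64)
        self.sp_j1 = np.array(sp_j1, dtype=np.int64)
        self.sp_gfrac = np.array(sp_gfrac, dtype=float)
        self.sp_K = np.array(sp_K, dtype=float)
        self.sp_l0 = np.array(sp_l0, dtype=float)
        self.sp_is_motor = np.array([k == "motor" for k, _ in self.spring_ids],
                                    dtype=bool)

        # boundary samples: per cylinder both endpoints and the midpoint
        self.bnd_i0 = np.repeat(self.cyl_pairs[:, 0], 3)
        self.bnd_i1 = np.repeat(self.cyl_pairs[:, 1], 3)
        self.bnd_t = np.tile(np.array([0.0, 0.5, 1.0]), len(self.cyl_pairs))

        self.use_vol = p.use_excluded_volume
        if self.use_vol:
            nodes, wts = leggauss(16)
            self._gl_s = 0.5 * (nodes + 1.0)
            self._gl_w = 0.5 * wts
            self._vol_pairs = self._neighbor_pairs(state)

    def _neighbor_pairs(self, state: NetworkState):
        """Non-adjacent cylinder pairs within the steric cutoff."""
        cyls = []
        for fid in sorted(state.filaments):
            f = state.filaments[fid]
            for i in range(len(f.cylinders)):
                cyls.append((fid, i))
        pairs = []
        mids = 0.5 * (self.x0[self.cyl_pairs[:, 0]] + self.x0[self.cyl_pairs[:, 1]])
        lens = np.linalg.norm(self.x0[self.cyl_pairs[:, 1]]
                              - self.x0[self.cyl_pairs[:, 0]], axis=1)
        cut = EXCLUDED_VOLUME_CUTOFF
        for a in range(len(cyls)):
            for b in range(a + 1, len(cyls)):
                fa, ia = cyls[a]
                fb, ib = cyls[b]
                if fa == fb and abs(ia - ib) <= 1:
                    continue
                if np.linalg.norm(mids[a] - mids[b]) < cut + 0.5 * (lens[a] + lens[b]):
                    pairs.append((a, b))
        return np.array(pairs, dtype=int).reshape(-1, 2)

    # ------------------------------------------------------------------
    def energy_and_grad(self, x: np.ndarray):
        """Return (EnergyBreakdown, gradient array of shape (n,3))."""
        if _HAVE_NUMBA:
            bnd = self.boundary
            U, g = _core_energy_grad(
                x, self.cyl_pairs[:, 0], self.cyl_pairs[:, 1], self.cyl_eq,
                self.mech.K_fil_str, self.mech.K_fil_bend,
                self.sp_i0, self.sp_i1, self.sp_frac,
                self.sp_j0, self.sp_j1, self.sp_gfrac,
                self.sp_K, self.sp_l0, self.sp_is_motor,
                self.bnd_i0, self.bnd_i1, self.bnd_t,
                bnd.shape == "sphere", bnd.radius,
                bnd.height / 2.0 if bnd.shape == "oblate" else bnd.radius,
                self.mech.eps_boundary, self.mech.lambda_screen, self.mech.a0,
                _BOUNDARY_EXP_MAX)
            br = EnergyBreakdown(U_fil_str=float(U[0]), U_fil_bend=float(U[1]),
                                 U_motor_str=float(U[3]),
                                 U_linker_str=float(U[4]),
                                 U_boundary=float(U[5]))
            if self.use_vol and len(self._vol_pairs):
                Uv, gv = self._vol_energy_grad(x)
                br.U_vol = Uv
                g = g + gv
            return br, g
        return self.energy_and_grad_numpy(x)

    def energy_and_grad_numpy(self, x: np.ndarray):
        """Pure-numpy reference path (identical results to the jitted
        kernel; kept as an independent implementation for cross-checks)."""
        g = np.zeros_like(x)
        br = EnergyBreakdown()
        K = self.mech

        if len(self.cyl_pairs):
            a = x[self.cyl_pairs[:, 0]]
            b = x[self.cyl_pairs[:, 1]]
            d = b - a
            l = np.linalg.norm(d, axis=1)
            dl = l - self.cyl_eq
            br.U_fil_str = float(0.5 * K.K_fil_str * np.sum(dl ** 2))
            with np.errstate(invalid="ignore", divide="ignore"):
                f = (K.K_fil_str * dl / np.where(l > 0, l, 1.0))[:, None] * d
            _scatter_add(g, self.cyl_pairs[:, 1], f)
            _scatter_add(g, self.cyl_pairs[:, 0], -f)

        if len(self.bend_triplets):
            p0 = x[self.bend_triplets[:, 0]]
            p1 = x[self.bend_triplets[:, 1]]
            p2 = x[self.bend_triplets[:, 2]]
            u = p1 - p0
            v = p2 - p1
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            inv = 1.0 / (nu * nv)
            c = np.clip(np.einsum("ij,ij->i", u, v) * inv, -1.0, 1.0)
            # theta0 = 0: U = K (1 - cos theta)
            br.U_fil_bend = float(K.K_fil_bend * np.sum(1.0 - c))
            dc_du = v * inv[:, None] - (c / nu ** 2)[:, None] * u
            dc_dv = u * inv[:, None] - (c / nv ** 2)[:, None] * v
            gu = -K.K_fil_bend * dc_du
            gv = -K.K_fil_bend * dc_dv
            _scatter_add(g, self.bend_triplets[:, 0], -gu)
            _scatter_add(g, self.bend_triplets[:, 1], gu - gv)
            _scatter_add(g, self.bend_triplets[:, 2], gv)

        if len(self.sp_K):
            pa = (1 - self.sp_frac)[:, None] * x[self.sp_i0] + self.sp_frac[:, None] * x[self.sp_i1]
            pb = (1 - self.sp_gfrac)[:, None] * x[self.sp_j0] + self.sp_gfrac[:, None] * x[self.sp_j1]
            d = pb - pa
            l = np.linalg.norm(d, axis=1)
            dl = l - self.sp_l0
            e = 0.5 * self.sp_K * dl ** 2
            is_motor = self.sp_is_motor
            br.U_motor_str = float(np.sum(e[is_motor]))
            br.U_linker_str = float(np.sum(e[~is_motor]))
            f = (self.sp_K * dl / np.where(l > 0, l, 1.0))[:, None] * d
            _scatter_add(g, self.sp_j0, (1 - self.sp_gfrac)[:, None] * f)
            _scatter_add(g, self.sp_j1, self.sp_gfrac[:, None] * f)
            _scatter_add(g, self.sp_i0, -(1 - self.sp_frac)[:, None] * f)
            _scatter_add(g, self.sp_i1, -self.sp_frac[:, None] * f)
            self._spring_tension = self.sp_K * dl

        if len(self.bnd_i0):
            t = self.bnd_t[:, None]
            pts = (1 - t) * x[self.bnd_i0] + t * x[self.bnd_i1]
            U_b, dU_dp = _boundary_energy_grad(pts, self.boundary, K)
            br.U_boundary = float(np.sum(U_b))
            _scatter_add(g, self.bnd_i0, (1 - t) * dU_dp)
            _scatter_add(g, self.bnd_i1, t * dU_dp)

        if self.use_vol and len(self._vol_pairs):
            Uv, gv = self._vol_energy_grad(x)
            br.U_vol = Uv
            g += gv

        return br, g

    def _vol_energy_grad(self, x: np.ndarray):
        s = self._gl_s
        w = self._gl_w
        U = 0.0
        g = np.zeros_like(x)
        Kv = self.mech.K_vol
        for a, b in self._vol_pairs:
            ia0, ia1 = self.cyl_pairs[a]
            ib0, ib1 = self.cyl_pairs[b]
            a0, a1 = x[ia0], x[ia1]
            b0, b1 = x[ib0], x[ib1]
            La = np.linalg.norm(a1 - a0)
            Lb = np.linalg.norm(b1 - b0)
            if La == 0 or Lb == 0:
                continue
            xi = a0[None, :] + s[:, None] * (a1 - a0)[None, :]
            yj = b0[None, :] + s[:, None] * (b1 - b0)[None, :]
            diff = xi[:, None, :] - yj[None, :, :]
            r2 = np.einsum("ijk,ijk->ij", diff, diff)
            inv4 = 1.0 / r2 ** 2
            S = np.einsum("i,j,ij->", w, w, inv4)
            U_pair = Kv * La * Lb * S
            if U_pair > EXCLUDED_VOLUME_CAP:
                U += EXCLUDED_VOLUME_CAP
                continue
            U += U_pair
            # dS/dpoints
            coef = -4.0 * inv4 / r2                      # d(r^-4)/d(diff) factor
            gd = (w[:, None] * w[None, :] * coef)[:, :, None] * diff
            gxi = gd.sum(axis=1)                         # (n,3) per xi node
            gyj = -gd.sum(axis=0)
            ua = (a1 - a0) / La
            ub = (b1 - b0) / Lb
            pref = Kv * La * Lb
            g[ia0] += pref * ((1 - s)[:, None] * gxi).sum(axis=0) - Kv * Lb * S * ua
            g[ia1] += pref * (s[:, None] * gxi).sum(axis=0) + Kv * Lb * S * ua
            g[ib0] += pref * ((1 - s)[:, None] * gyj).sum(axis=0) - Kv * La * S * ub
            g[ib1] += pref * (s[:, None] * gyj).sum(axis=0) + Kv * La * S * ub
        return float(U), g

    # ------------------------------------------------------------------
    def write_back(self, x: np.ndarray) -> None:
        """Copy minimized vertex coordinates into the filament cylinders."""
        for fid, base in self.fil_base.items():
            f = self.state.filaments[fid]
            for i, c in enumerate(f.cylinders):
                c.p_minus = x[base + i].copy()
                c.p_plus = x[base + i + 1].copy()

    def force_field(self, x: np.ndarray) -> ForceField:
        """Forces at configuration x, resolved for the rate laws."""
        _, g = self.energy_and_grad(x)
        ff = ForceField(vertex_forces=-g)
        mech = self.mech
        for fid, base in self.fil_base.items():
            f = self.state.filaments[fid]
            nv = len(f.cylinders)
            # barbed end: load = boundary force component opposing growth
            p_plus = x[base + nv]
            p_prev = x[base + nv - 1]
            axis = p_plus - p_prev
            n = np.linalg.norm(axis)
            if n > 0:
                axis = axis / n
                fb = -_boundary_energy_grad(p_plus[None, :], self.boundary, mech)[1][0]
                ff.be_load[fid] = max(0.0, -float(np.dot(fb, axis)))
            else:
                ff.be_load[fid] = 0.0
            p_minus = x[base]
            p_next = x[base + 1]
            axis_p = p_minus - p_next
            n = np.linalg.norm(axis_p)
            if n > 0:
                axis_p = axis_p / n
                fb = -_boundary_energy_grad(p_minus[None, :], self.boundary, mech)[1][0]
                ff.pe_load[fid] = max(0.0, -float(np.dot(fb, axis_p)))
            else:
                ff.pe_load[fid] = 0.0
        if len(self.sp_K):
            pa = (1 - self.sp_frac)[:, None] * x[self.sp_i0] + self.sp_frac[:, None] * x[self.sp_i1]
            pb = (1 - self.sp_gfrac)[:, None] * x[self.sp_j0] + self.sp_gfrac[:, None] * x[self.sp_j1]
            l = np.linalg.norm(pb - pa, axis=1)
            F = self.sp_K * (l - self.sp_l0)
            for (kind, eid), t in zip(self.spring_ids, F):
                if kind == "motor":
                    ff.motor_tension[eid] = float(t)
                else:
                    ff.linker_tension[eid] = float(t)
        return ff


#: exponent clamp for the boundary repulsion (keeps deep-penetration
#: configurations finite; forces remain astronomically larger than any
#: other term, so minimization behavior is unchanged)
_BOUNDARY_EXP_MAX = 50.0


def _boundary_energy_grad(pts: np.ndarray, geom: BoundaryGeometry,
                          mech: MechParams):
    """Boundary repulsion energy and dU/dp for an array of points."""
    eps, lam, a0 = mech.eps_boundary, mech.lambda_screen, mech.a0
    if geom.shape == "sphere":
        r = np.linalg.norm(pts, axis=1)
        d = geom.radius - r
        U = eps * np.exp(np.minimum(-(d - a0) / lam, _BOUNDARY_EXP_MAX))
        # dU/dp = -U/lam * dd/dp with dd/dp = -p/|p|
        dU = (U / lam)[:, None] * (pts / np.where(r > 0, r, 1.0)[:, None])
        return U, dU
    r_xy = np.hypot(pts[:, 0], pts[:, 1])
    d_side = geom.radius - r_xy
    d_cap = geom.height / 2.0 - np.abs(pts[:, 2])
    side = d_side < d_cap
    d = np.where(side, d_side, d_cap)
    U = eps * np.exp(np.minimum(-(d - a0) / lam, _BOUNDARY_EXP_MAX))
    dd_dp = np.zeros_like(pts)
    safe = np.where(r_xy > 0, r_xy, 1.0)
    dd_dp[side, 0] = -pts[side, 0] / safe[side]
    dd_dp[side, 1] = -pts[side, 1] / safe[side]
    dd_dp[~side, 2] = -np.sign(pts[~side, 2])
    dU = (-U / lam)[:, None] * dd_dp
    return U, dU


# ---------------------------------------------------------------------------
# FIRE minimizer

@dataclass
class MinimizeResult:
    breakdown: EnergyBreakdown
    forces: ForceField
    converged: bool
    n_iter: int
    max_force: float


def fire_minimize(system: MechanicalSystem, tol: float = 1.0,
                  max_iter: int = 5000) -> tuple[np.ndarray, EnergyBreakdown, bool, int, float]:
    """FIRE (fast inertial relaxation engine) minimization.

    Returns (x, breakdown, converged, n_iter, max_force). Robust for stiff
    bead-rod systems; step size adapts, displacement per step is capped.
    """
    x = system.x0.copy()
    if x.size == 0:
        br, _ = system.energy_and_grad(x)
        return x, br, True, 0, 0.0
    v = np.zeros_like(x)
    dt = 0.01
    dt_max = 0.15
    disp_cap = 1.0                   # nm per step
    alpha = 0.1
    n_pos = 0
    br, g = system.energy_and_grad(x)
    F = -g
    fmax = np.abs(F).max()
    it = 0
    while fmax > tol and it < max_iter:
        P = float(np.sum(F * v))
        if P > 0:
            n_pos += 1
            vn = math.sqrt(float(np.sum(v * v)))
            fn = math.sqrt(float(np.sum(F * F)))
            if fn > 0:
                v = (1 - alpha) * v + (alpha * vn / fn) * F
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_pos = 0
        v = v + dt * F
        dx = dt * v
        m = np.abs(dx).max()
        if not np.isfinite(m):
            # force blow-up (deep boundary penetration): restart gently
            v[:] = 0.0
            dt = 0.001
            dirn = np.where(np.isfinite(F), F, 0.0)
            nrm = np.abs(dirn).max()
            dx = (disp_cap / nrm) * dirn if nrm > 0 else 0.0
        elif m > disp_cap:
            dx *= disp_cap / m
        x = x + dx
        br, g = system.energy_and_grad(x)
        F = -g
        fmax = np.abs(F).max()
        it += 1
    return x, br, bool(fmax <= tol), it, float(fmax)


def minimize(state: NetworkState, tol: float = 1.0,
             max_iter: int = 5000) -> MinimizeResult:
    """Relax the network to a local energy minimum and report forces.

    Chemistry-owned quantities (monomer counts, topology, bound species)
    are untouched; only coordinates move. Returns best-so-far with
    ``converged=False`` if the iteration cap is hit.
    """
    fuse_degenerate_cylinders(state)
    system = MechanicalSystem(state)
    br0, _ = system.energy_and_grad(system.x0)
    x, br, conv, it, fmax = fire_minimize(system, tol=tol, max_iter=max_iter)
    if br.U_total > br0.U_total + 1e-9:
        # never accept an energy increase over the input configuration
        x, br = system.x0, br0
    system.write_back(x)
    ff = system.force_field(x)
    return MinimizeResult(breakdown=br, forces=ff, converged=conv,
                          n_iter=it, max_force=fmax)


def fuse_degenerate_cylinders(state: NetworkState, min_length: float = 0.1) -> int:
    """Merge cylinders shorter than ``min_length`` nm into a neighbor.

    Only performed when the merged monomer count still fits one cylinder;
    binding sites on the removed cylinder are remapped to the absorber.
    Returns the number of fusions performed.
    """
    fused = 0
    for f in state.filaments.values():
        if len(f.cylinders) < 2:
            continue
        i = 0
        while i < len(f.cylinders) and len(f.cylinders) > 1:
            c = f.cylinders[i]
            if c.length >= min_length:
                i += 1
                continue
            j = i + 1 if i + 1 < len(f.cylinders) else i - 1
            nb = f.cylinders[j]
            if c.n_monomers + nb.n_monomers > 40:
                i += 1
                continue
            nb.n_monomers += c.n_monomers
            if j > i:
                nb.p_minus = c.p_minus.copy()
            else:
                nb.p_plus = c.p_plus.copy()
            _remap_sites(state, f.fid, c.cid, nb.cid)
            del f.cylinders[i]
            fused += 1
        # ends may have shrunk; nothing else to fix here
    return fused


def _remap_sites(state: NetworkState, fid: int, old_cid: int, new_cid: int) -> None:
    from .state import BindingSite
    def remap(site):
        if site.fid == fid and site.cid == old_cid:
            return BindingSite(fid, new_cid, site.site_index)
        return site
    for m in state.motors.values():
        m.site_a = remap(m.site_a)
        m.site_b = remap(m.site_b)
    for l in state.linkers.values():
        l.site_a = remap(l.site_a)
        l.site_b = remap(l.site_b)
    state.motor_sites = {remap(s) for s in state.motor_sites}
    state.linker_sites = {remap(s) for s in state.linker_sites}
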