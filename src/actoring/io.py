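"""Configuration parsing, trajectory file IO, and run manifests.

The trajectory container is HDF5 (one group per snapshot); its schema is
documented in ``docs/trajectory_schema.md``. Configuration files are YAML
with sections mirroring the parameter dataclasses; unknown keys are
rejected and missing keys fall back to the published defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time

import h5py
import numpy as np
import yaml

from .params import Params, MechParams, ChemParams, MechanoChemParams
from .protocol import ProtocolConfig
from .state import (BoundaryGeometry, Cylinder, Filament, MotorEnsemble,
                    Linker, BindingSite, Snapshot, Trajectory, SPECIES)

FORMAT_VERSION = 1

_CONFIG_SECTIONS = {
    "mech": MechParams,
    "chem": ChemParams,
    "mechanochem": MechanoChemParams,
}
_PROTOCOL_KEYS = {f.name for f in dataclasses.fields(ProtocolConfig)} - {"params", "schedule"}
_PARAMS_KEYS = {"compartment_edge", "binding_site_fractions", "motor_span",
                "linker_span", "use_excluded_volume"}


def load_config(path) -> ProtocolConfig:
    """Load and validate a YAML run configuration.

    Unknown keys raise; omitted keys take the published defaults (e.g. an
    empty file yields K_fil_bend = 672 pN·nm and the full Table-default
    rate set).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    cfg = ProtocolConfig()
    for section, payload in raw.items():
        if section in _CONFIG_SECTIONS:
            target = getattr(cfg.params, "mechchem" if section == "mechanochem" else section)
            valid = {f.name for f in dataclasses.fields(target)}
            for k, v in (payload or {}).items():
                if k not in valid:
                    raise KeyError(f"unknown key {section}.{k}")
                setattr(target, k, v)
        elif section == "params":
            for k, v in (payload or {}).items():
                if k not in _PARAMS_KEYS:
                    raise KeyError(f"unknown key params.{k}")
                setattr(cfg.params, k, tuple(v) if isinstance(v, list) else v)
        elif section == "protocol":
            for k, v in (payload or {}).items():
                if k not in _PROTOCOL_KEYS:
                    raise KeyError(f"unknown key protocol.{k}")
                setattr(cfg, k, v)
        elif section == "schedule":
            sched = []
            for entry in payload or []:
                sched.append((float(entry["time"]),
                              tuple(entry["action"])))
            cfg.schedule = sorted(sched, key=lambda x: x[0])
        else:
            raise KeyError(f"unknown config section {section!r}")
    issues = cfg.params.validate()
    for name in ("conc_G", "conc_formin"):
        if getattr(cfg, name) < 0:
            issues.append(f"{name} must be non-negative")
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    return cfg


def config_hash(cfg: ProtocolConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_manifest(cfg: ProtocolConfig, seed: int, outputs: list) -> dict:
    from . import __version__
    return {"config_hash": config_hash(cfg), "code_version": __version__,
            "seed": seed, "created": _time.strftime("%Y-%m-%dT%H:%M:%S"),
            "params": dataclasses.asdict(cfg), "outputs": list(outputs)}


# -- trajectory files -------------------------------------------------------

def write_trajectory(path, traj: Trajectory) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["meta"] = json.dumps(traj.meta, default=str)
        b = traj.snapshots[0].boundary if traj.snapshots else None
        if b is not None:
            h5.attrs["boundary"] = json.dumps(
                {"shape": b.shape, "diameter": b.diameter,
                 "height": b.height, "a0": b.a0})
        for i, s in enumerate(traj.snapshots):
            g = h5.create_group(f"snap_{i:06d}")
            g.attrs["time"] = s.time
            g.attrs["counters"] = json.dumps(
                [s.tot_be_added, s.tot_be_removed, s.tot_pe_added, s.tot_pe_removed])
            g.attrs["energy"] = json.dumps(s.energy)
            fg = g.create_group("filaments")
            for fid, f in s.filaments.items():
                rec = fg.create_group(str(fid))
                rec.attrs["barbed_state"] = f.barbed_state
                rec.attrs["interval"] = (f.L, f.R)
                rec.attrs["counters"] = (f.be_added, f.be_removed,
                                         f.pe_added, f.pe_removed)
                rec.create_dataset("cid", data=[c.cid for c in f.cylinders])
                rec.create_dataset("n_monomers",
                                   data=[c.n_monomers for c in f.cylinders])
                pts = np.array([f.cylinders[0].p_minus]
                               + [c.p_plus for c in f.cylinders])
                rec.create_dataset("vertices", data=pts)
            mg = g.create_group("motors")
            for mid, m in s.motors.items():
                rec = mg.create_group(str(mid))
                rec.attrs["n_heads"] = m.n_heads
                rec.attrs["eq_length"] = m.eq_length
                rec.attrs["site_a"] = (m.site_a.fid, m.site_a.cid, m.site_a.site_index)
                rec.attrs["site_b"] = (m.site_b.fid, m.site_b.cid, m.site_b.site_index)
            lg = g.create_group("linkers")
            for lid, l in s.linkers.items():
                rec = lg.create_group(str(lid))
                rec.attrs["eq_length"] = l.eq_length
                rec.attrs["site_a"] = (l.site_a.fid, l.site_a.cid, l.site_a.site_index)
                rec.attrs["site_b"] = (l.site_b.fid, l.site_b.cid, l.site_b.site_index)
            cg = g.create_group("grid")
            for sp in SPECIES:
                if sp in s.grid_counts:
                    cg.create_dataset(sp, data=s.grid_counts[sp])


def read_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        version = h5.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported trajectory format version {version!r}")
        meta = json.loads(h5.attrs.get("meta", "{}"))
        bnd_raw = h5.attrs.get("boundary")
        boundary = BoundaryGeometry(**json.loads(bnd_raw)) if bnd_raw else \
            BoundaryGeometry()
        traj = Trajectory(meta=meta)
        for name in sorted(k for k in h5.keys() if k.startswith("snap_")):
            g = h5[name]
            filaments = {}
            for fid_s, rec in g["filaments"].items():
                fid = int(fid_s)
                cids = rec["cid"][:]
                nm = rec["n_monomers"][:]
                verts = rec["vertices"][:]
                cylinders = [Cylinder(p_minus=verts[i], p_plus=verts[i + 1],
                                      n_monomers=int(nm[i]), cid=int(cids[i]))
                             for i in range(len(cids))]
                L, R = (int(v) for v in rec.attrs["interval"])
                ctr = [int(v) for v in rec.attrs["counters"]]
                f = Filament(fid=fid, cylinders=cylinders,
                             barbed_state=str(rec.attrs["barbed_state"]),
                             L=L, R=R, be_added=ctr[0], be_removed=ctr[1],
                             pe_added=ctr[2], pe_removed=ctr[3])
                f._next_cid = int(max(cids)) + 1 if len(cids) else 0
                filaments[fid] = f
            motors = {}
            for mid_s, rec in g["motors"].items():
                sa = BindingSite(*(int(v) for v in rec.attrs["site_a"]))
                sb = BindingSite(*(int(v) for v in rec.attrs["site_b"]))
                motors[int(mid_s)] = MotorEnsemble(
                    mid=int(mid_s), n_heads=int(rec.attrs["n_heads"]),
                    site_a=sa, site_b=sb,
                    eq_length=float(rec.attrs["eq_length"]))
            linkers = {}
            for lid_s, rec in g["linkers"].items():
                sa = BindingSite(*(int(v) for v in rec.attrs["site_a"]))
                sb = BindingSite(*(int(v) for v in rec.attrs["site_b"]))
                linkers[int(lid_s)] = Linker(
                    lid=int(lid_s), site_a=sa, site_b=sb,
                    eq_length=float(rec.attrs["eq_length"]))
            counters = json.loads(g.attrs["counters"])
            traj.append(Snapshot(
                time=float(g.attrs["time"]), boundary=boundary,
                filaments=filaments, motors=motors, linkers=linkers,
                grid_counts={sp: g["grid"][sp][:] for sp in g["grid"].keys()},
                energy=json.loads(g.attrs["energy"]),
                tot_be_added=counters[0], tot_be_removed=counters[1],
                tot_pe_added=counters[2], tot_pe_removed=counters[3]))
    return traj
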