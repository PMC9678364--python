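# Trajectory file schema (HDF5, format_version = 1)

Written by `actoring.io.write_trajectory`, read by `read_trajectory`.

## Root attributes
- `format_version` (int): schema version; readers reject mismatches.
- `meta` (JSON string): run metadata (seed, chemistry window, status, ...).
- `boundary` (JSON string): `{shape, diameter, height, a0}` in nm.

## Groups `snap_000000`, `snap_000001`, ... (one per snapshot)
Attributes:
- `time` (float, s)
- `counters` (JSON `[be_added, be_removed, pe_added, pe_removed]`):
  system-wide cumulative end-event counts (monotone, survive filament
  destruction)
- `energy` (JSON dict): per-term energy breakdown in pN·nm
  (`U_fil_str`, `U_fil_bend`, `U_vol`, `U_motor_str`, `U_linker_str`,
  `U_boundary`, `U_total`, `U_mech`)

### `filaments/<fid>/`
- attrs `barbed_state` ("BE" free / "FBE" formin-bound), `interval`
  `(L, R)` — the lab-frame monomer index interval [L, R) used for
  subunit-identity (FRAP-like) bookkeeping — and per-filament cumulative
  `counters`.
- datasets `cid` (stable cylinder ids, pointed→barbed), `n_monomers`
  (per cylinder, 1–40), `vertices` ((n_cyl+1, 3) nm; consecutive
  cylinders share vertices).

### `motors/<mid>/`, `linkers/<lid>/`
- attrs `n_heads` (motors), `eq_length` (nm), `site_a`, `site_b` =
  `(fid, cid, site_index)` binding-site references (site_index indexes the
  fractional positions {1/8, 3/8, 5/8, 7/8} along the cylinder axis).

### `grid/`
- one integer dataset per diffusing species (`G`, `formin`,
  `intermediate`, `NMII`, `linker`) with the per-compartment copy
  numbers.
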