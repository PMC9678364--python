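"""Force-dependent reaction rates.

Four laws couple the relaxed mechanical forces back into the chemistry:

- Brownian ratchet: a compressive boundary load on a polymerizing tip
  suppresses monomer addition exponentially.
- Slip bond: tension on a crosslinker accelerates its unbinding
  exponentially; compression has no effect.
- Catch bond (parallel cluster model): tension on an NMII ensemble
  *reduces* its unbinding rate; the rate also scales as 1/N_heads.
- Hill force-velocity: tension opposing the walking direction slows motor
  stepping, reaching zero at the ensemble stall force N_heads * F_stall.

Rates are recomputed only at protocol boundaries, after each energy
minimization — never mid-chemistry-window.
"""

from __future__ import annotations

import math
import warnings


def ratchet_poly_rate(k0: float, F_ext: float, F_poly0: float = 1.5) -> float:
    """Brownian-ratchet polymerization rate: k0 * exp(-F_ext / F_poly0).

    F_ext is the compressive boundary load along the filament axis at the
    polymerizing end (pN, >= 0; zero away from the boundary). Negative
    input is clamped to zero with a warning.
    """
    if F_ext < 0:
        warnings.warn("negative polymerization load clamped to 0")
        F_ext = 0.0
    return k0 * math.exp(-F_ext / F_poly0)


def slip_unbind_rate(k0: float, F_stretch: float,
                     F_linker_unbind: float = 17.2) -> float:
    """Slip-bond unbinding: k0 * exp(max(F,0) / F_linker_unbind).

    Compression (F_stretch < 0) does not trigger the slip bond.
    """
    return k0 * math.exp(max(F_stretch, 0.0) / F_linker_unbind)


def catch_unbind_rate(k0: float, F_ext: float, n_heads: int,
                      beta: float = 0.2, F_nmii_unbind: float = 20.0) -> float:
    """Catch-bond NMII ensemble unbinding rate.

    beta * k0 / N_heads * exp(-F_ext / (N_heads * F_nmii_unbind)), with
    F_ext the total tension on the ensemble (pN, tension only).
    """
    if n_heads < 1:
        raise ValueError("n_heads must be >= 1")
    F = max(F_ext, 0.0)
    return beta * k0 / n_heads * math.exp(-F / (n_heads * F_nmii_unbind))


def hill_walk_rate(k0_walk: float, F_pull: float, n_heads: int,
                   F_stall: float = 12.62, xi: float = 0.1) -> float:
    """Hill-type force-velocity walking rate, floored at zero.

    k0 * (F_stall - F_pull/N) / (F_stall + F_pull/(N*xi)), where F_pull is
    the component of motor tension opposing the step (pN, >= 0). The rate
    equals k0 unloaded and hits exactly 0 at F_pull = N_heads * F_stall.
    """
    if n_heads < 1:
        raise ValueError("n_heads must be >= 1")
    F = max(F_pull, 0.0)
    num = F_stall - F / n_heads
    if num <= 0:
        return 0.0
    return k0_walk * num / (F_stall + F / (n_heads * xi))
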