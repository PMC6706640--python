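"""Two-state protein-ligand binding equilibrium and fast-exchange relaxation.

The ligand-detected screen works because a small molecule that transiently
binds a large protein inherits, in proportion to its bound fraction, the
protein's fast rotating-frame relaxation.  Under fast exchange the observed
relaxation rate is the population-weighted average of the free and bound
rates, so the bound fraction from the standard binding quadratic is the
single quantity that couples the thermodynamics (KD) to the spectroscopy.
"""

from __future__ import annotations

import math


def bound_fraction(p_tot: float, l_tot: float, kd: float) -> float:
    """Fraction of ligand bound at total protein ``p_tot`` and total ligand
    ``l_tot`` (same concentration units) for dissociation constant ``kd``.

    Solves the two-state equilibrium (P + L <-> PL, KD = [P][L]/[PL]) exactly:
    [PL] is the smaller root of x**2 - (P + L + KD) x + P*L = 0, evaluated in
    the numerically stable form 2PL / (b + sqrt(b^2 - 4PL)).

    ``kd`` may be ``math.inf`` (non-binder, returns 0).  KD -> 0 gives the
    stoichiometric limit min(P, L)/L.
    """
    if p_tot <= 0 or l_tot <= 0:
        raise ValueError("concentrations must be positive")
    if kd < 0:
        raise ValueError("KD must be positive (or +inf for a non-binder)")
    if math.isinf(kd):
        return 0.0
    b = p_tot + l_tot + kd
    disc = b * b - 4.0 * p_tot * l_tot
    # disc >= (p_tot - l_tot)^2 + kd^2 >= 0 analytically; clamp rounding
    root = math.sqrt(max(disc, 0.0))
    complex_conc = 2.0 * p_tot * l_tot / (b + root)
    frac = complex_conc / l_tot
    return min(max(frac, 0.0), 1.0)


def observed_relaxation(p_bound: float, r_free: float, r_bound: float) -> float:
    """Population-averaged relaxation rate under fast exchange (1/s).

    A ligand spending fraction ``p_bound`` of its time on the protein relaxes
    at (1 - p_bound) * r_free + p_bound * r_bound; monotone in ``p_bound``.
    """
    if not 0.0 <= p_bound <= 1.0:
        raise ValueError("p_bound must lie in [0, 1]")
    if r_free <= 0 or r_bound < r_free:
        raise ValueError("rates must satisfy r_bound >= r_free > 0")
    return (1.0 - p_bound) * r_free + p_bound * r_bound
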