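"""Polymorph free-energy ranking and sensitivity probes.

ΔG(T) = G_B(T) − G_A(T) per molecule decides relative stability: a pair
is *monotropic* when the sign never changes below melting and
*enantiotropic* when a stability crossover exists.  The ΔG slope is
governed by −ΔS and its curvature by the heat-capacity hierarchy, which
motivates the two sensitivity probes: a constant entropy offset (a
residual-entropy hypothesis) and a heat-capacity scale factor
(re-integrated to S and H from the 0 K anchors).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import ThermoTable
from .exceptions import InputError

__all__ = [
    "RankingResult",
    "rank_polymorphs",
    "sensitivity_entropy_offset",
    "sensitivity_cp_scale",
    "refine_ranking",
    "DEGENERACY_TOL_KJ",
]

#: |ΔG| below this (kJ mol⁻¹) is within sub-kJ experimental uncertainty
#: and counts as degenerate for the classification.
DEGENERACY_TOL_KJ = 0.01


@dataclass(frozen=True)
class RankingResult:
    """ΔG/ΔH/TΔS of polymorph B relative to A on a temperature grid.

    Positive ΔG means B is the metastable form.  Units: kJ mol⁻¹ per
    molecule; ``crossing_temperatures`` in K.
    """

    polymorph_labels: tuple[str, str]
    temperatures: np.ndarray
    delta_g: np.ndarray
    delta_h: np.ndarray
    t_delta_s: np.ndarray
    crossing_temperatures: tuple[float, ...]
    relationship: str
    t_range: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("temperatures", "delta_g", "delta_h", "t_delta_s"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))


def _classify(temperatures, delta_g, t_range):
    """Crossings (linear interpolation) and the stability relationship."""
    lo, hi = t_range
    mask = (temperatures >= lo - 1e-9) & (temperatures <= hi + 1e-9)
    t = temperatures[mask]
    dg = delta_g[mask]
    crossings = []
    for i in range(t.size - 1):
        a, b = dg[i], dg[i + 1]
        if a * b < 0.0:
            crossings.append(float(t[i] - a * (t[i + 1] - t[i]) / (b - a)))
        elif a == 0.0 and 0 < i and dg[i - 1] * b < 0.0:
            crossings.append(float(t[i]))  # isolated zero with a sign change
    if np.max(np.abs(dg)) < DEGENERACY_TOL_KJ:
        relationship = "indeterminate"
    elif crossings:
        relationship = "enantiotropic"
    else:
        relationship = "monotropic"
    return tuple(crossings), relationship


def rank_polymorphs(
    table_a: ThermoTable,
    table_b: ThermoTable,
    t_range: tuple[float, float] | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> RankingResult:
    """Rank two polymorphs by Gibbs energy and enthalpy differences.

    Both tables must share the temperature grid and pressure and already
    be per-molecule normalized.  ``t_range`` restricts the classification
    window (typically [0, T_fus]); crossings are located by linear
    interpolation between grid points.
    """
    if table_a.temperatures.shape != table_b.temperatures.shape or np.any(
        table_a.temperatures != table_b.temperatures
    ):
        raise InputError("incompatible tables: temperature grids differ")
    if table_a.pressure != table_b.pressure:
        raise InputError("incompatible tables: pressures differ")

    t = table_a.temperatures
    dg = table_b.g - table_a.g
    ds = (table_b.s - table_a.s) / 1000.0          # kJ K⁻¹ mol⁻¹
    tds = t * ds
    dh = dg + tds                                   # H = G + T·S per table
    if t_range is None:
        t_range = (float(t[0]), float(t[-1]))
    crossings, relationship = _classify(t, dg, t_range)
    return RankingResult(
        polymorph_labels=tuple(labels),
        temperatures=t,
        delta_g=dg,
        delta_h=dh,
        t_delta_s=tds,
        crossing_temperatures=crossings,
        relationship=relationship,
        t_range=(float(t_range[0]), float(t_range[1])),
    )


def sensitivity_entropy_offset(table: ThermoTable, delta_s: float) -> ThermoTable:
    """Add a constant entropy offset δS (J K⁻¹ mol⁻¹ per molecule).

    Probes a hypothetical residual entropy: S gains δS at every T, G loses
    T·δS, H is unchanged.  Against an unmodified partner this tilts the
    ΔG(T) slope by exactly −δS.
    """
    t = table.temperatures
    return table.replace(
        s=table.s + delta_s,
        g=table.g - t * delta_s / 1000.0,
    )


def sensitivity_cp_scale(table: ThermoTable, factor: float) -> ThermoTable:
    """Scale C_p by a constant factor and re-integrate S, H and G.

    With S(T) = S(0) + ∫₀ᵀ C_p/T′ dT′ and H(T) = H(0) + ∫₀ᵀ C_p dT′,
    scaling C_p by f scales both integrals: S → S(0) + f·(S − S(0)) and
    H → H(0) + f·(H − H(0)), with G = H − T·S recomputed.  The table must
    start at 0 K so the anchors are available.
    """
    if factor <= 0:
        raise InputError("scale factor must be positive")
    if table.temperatures[0] != 0.0:
        raise InputError("cannot re-integrate: table does not start at 0 K")
    s0 = table.s[0]
    h0 = table.h[0]
    s_new = s0 + factor * (table.s - s0)
    h_new = h0 + factor * (table.h - h0)
    g_new = h_new - table.temperatures * s_new / 1000.0
    return table.replace(cp=factor * table.cp, s=s_new, h=h_new, g=g_new)


def refine_ranking(result: RankingResult, delta_e_correction: float) -> RankingResult:
    """Apply a temperature-independent electronic-energy correction.

    A fragment-refined lattice-energy difference shifts both ΔG and ΔH by
    the same constant (kJ mol⁻¹ per molecule); TΔS is untouched and the
    crossings and relationship are recomputed.
    """
    dg = result.delta_g + delta_e_correction
    dh = result.delta_h + delta_e_correction
    crossings, relationship = _classify(result.temperatures, dg, result.t_range)
    return replace(
        result,
        delta_g=dg,
        delta_h=dh,
        crossing_temperatures=crossings,
        relationship=relationship,
    )
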