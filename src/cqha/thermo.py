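"""Harmonic-oscillator thermodynamics and the F(T, V) surface.

For each volume the phonons define a vibrational Helmholtz energy

    A_vib(T, V) = Σ_q w_q Σ_i [ N_A·h·ν_i/2 + R·T·ln(1 − e^(−h·ν_i/k_B·T)) ],

which added to the static E_el(V) gives F(T, V).  Each isotherm F(V) is
refit with the Murnaghan form; its analytic minimum (optionally under an
external pressure p) yields the equilibrium volume V_eq(T, p) and the
Gibbs energy G(T, p) = F(T, V_eq) + p·V_eq, from which entropy, enthalpy,
heat capacities, expansivity and compressibility follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import GPA_A3_TO_KJMOL, R_GAS, THZ_TO_K, THZ_TO_KJMOL
from .datamodel import EVCurve, FrequencySet, MurnaghanFit, ThermoTable
from .eos import bulk_modulus, eval_murnaghan, fit_murnaghan, pressure_volume
from .exceptions import InputError, NumericalError

__all__ = [
    "vibrational_helmholtz",
    "vibrational_entropy",
    "vibrational_cv",
    "zero_point_energy",
    "FreeEnergySurface",
    "build_surface",
    "equilibrium_state",
    "thermo_properties",
    "linear_expansion",
]


def _check_freqs(freq_sets: FrequencySet) -> None:
    for _, f in freq_sets:
        if np.any(np.asarray(f) <= 0):
            raise NumericalError("unfiltered imaginary mode reached thermodynamics")


def zero_point_energy(freq_sets: FrequencySet) -> float:
    """ZPE = Σ_q w_q Σ_i N_A·h·ν_i/2 in kJ mol⁻¹ per cell."""
    _check_freqs(freq_sets)
    return float(sum(w * 0.5 * THZ_TO_KJMOL * np.sum(f) for w, f in freq_sets))


def vibrational_helmholtz(freq_sets: FrequencySet, t: float) -> float:
    """A_vib(T) in kJ mol⁻¹ per cell; equals the ZPE at T = 0."""
    if t < 0:
        raise InputError("temperature must be nonnegative")
    a = zero_point_energy(freq_sets)
    if t == 0:
        return a
    for w, f in freq_sets:
        x = THZ_TO_K * np.asarray(f) / t
        term = np.where(x < 700.0, np.log1p(-np.exp(-np.minimum(x, 700.0))), 0.0)
        a += w * R_GAS * t * float(np.sum(term)) / 1000.0
    return float(a)


def vibrational_entropy(freq_sets: FrequencySet, t: float) -> float:
    """Harmonic-oscillator entropy, J K⁻¹ mol⁻¹ per cell; 0 at T = 0."""
    if t < 0:
        raise InputError("temperature must be nonnegative")
    _check_freqs(freq_sets)
    if t == 0:
        return 0.0
    s = 0.0
    for w, f in freq_sets:
        x = THZ_TO_K * np.asarray(f) / t
        x = np.minimum(x, 700.0)
        s += w * R_GAS * float(
            np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x)))
        )
    return float(s)


def vibrational_cv(freq_sets: FrequencySet, t: float) -> float:
    """Harmonic C_v = R·Σ w·(x/2 / sinh(x/2))², J K⁻¹ mol⁻¹ per cell."""
    if t < 0:
        raise InputError("temperature must be nonnegative")
    _check_freqs(freq_sets)
    if t == 0:
        return 0.0
    cv = 0.0
    for w, f in freq_sets:
        x = THZ_TO_K * np.asarray(f) / t
        half = np.minimum(0.5 * x, 350.0)
        cv += w * R_GAS * float(np.sum((half / np.sinh(half)) ** 2))
    return float(cv)


@dataclass
class FreeEnergySurface:
    """F(T, V) = E_el(V) + A_vib(T, V) with per-isotherm Murnaghan fits.

    Keeps the ingredient callables so states at off-grid temperatures
    (needed for the 1 K finite-difference stencils) can be evaluated and
    cached on demand.
    """

    temperatures: np.ndarray
    volumes: np.ndarray
    f_values: np.ndarray                      # (n_T, n_V), kJ mol⁻¹ per cell
    e_of_v: "callable"
    freqs_of_v: "callable"
    _fits: dict = field(default_factory=dict, repr=False)

    def isotherm_fit(self, t: float) -> MurnaghanFit:
        key = float(t)
        if key not in self._fits:
            f_row = self._f_row(key)
            curve = EVCurve(self.volumes, f_row, level_label=f"F({t} K)")
            if not curve.has_interior_minimum:
                warnings.warn(
                    f"thermal expansion beyond grid at T = {t} K: "
                    "isotherm minimum not bracketed, fit extrapolated",
                    stacklevel=2,
                )
                self._fits[key] = _fit_unbracketed(curve)
            else:
                self._fits[key] = fit_murnaghan(curve)
        return self._fits[key]

    def _f_row(self, t: float) -> np.ndarray:
        e = np.asarray(self.e_of_v(self.volumes), dtype=float)
        a = np.array(
            [vibrational_helmholtz(self.freqs_of_v(v), t) for v in self.volumes]
        )
        return e + a


def _fit_unbracketed(curve: EVCurve):
    """Murnaghan fit without the interior-minimum guard (flagged upstream)."""
    from scipy.optimize import least_squares

    from .eos import _jacobian, _polish, murnaghan_energy

    v, e = curve.volumes, curve.energies
    coef = np.polyfit(v, e, 2)
    if coef[0] <= 0:
        raise NumericalError("eos fit failed: isotherm is not convex")
    v0_init = float(np.clip(-coef[1] / (2 * coef[0]), 0.5 * v[0], 2.0 * v[-1]))
    b0_init = max(2.0 * coef[0] * v0_init / GPA_A3_TO_KJMOL, 1e-3)
    p0 = [float(np.polyval(coef, v0_init)), v0_init, b0_init, 4.0]
    sol = least_squares(
        lambda p: murnaghan_energy(v, *p) - e, p0,
        jac=lambda p: _jacobian(v, *p),
        bounds=([-np.inf, 1e-6, 1e-9, 1 + 1e-9], [np.inf, np.inf, np.inf, 20.0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    params = _polish(v, e, sol.x)
    rms = float(np.sqrt(np.mean((murnaghan_energy(v, *params) - e) ** 2)))
    return MurnaghanFit(*map(float, params), rms)


def build_surface(
    e_of_v, freqs_of_v, volumes, temperatures
) -> FreeEnergySurface:
    """Evaluate F(T, V) on a grid and refit every isotherm.

    The volume grid must bracket the free-energy minimum at every
    temperature (a warning is issued and the fit extrapolated otherwise).
    """
    volumes = np.asarray(volumes, dtype=float)
    temperatures = np.asarray(temperatures, dtype=float)
    if volumes.size < 5:
        raise InputError("insufficient points: surface needs >= 5 volumes")
    surf = FreeEnergySurface(
        temperatures=temperatures,
        volumes=volumes,
        f_values=np.empty((temperatures.size, volumes.size)),
        e_of_v=e_of_v,
        freqs_of_v=freqs_of_v,
    )
    for i, t in enumerate(temperatures):
        surf.f_values[i] = surf._f_row(float(t))
        surf.isotherm_fit(float(t))
    return surf


def equilibrium_state(
    surface: FreeEnergySurface, t: float, p: float = 0.0
) -> dict:
    """Equilibrium volume and Gibbs energy (per cell) at (T, p).

    V_eq minimizes F(T, V) + p·V via the closed-form Murnaghan inversion
    of the refitted isotherm; G = F(V_eq) + p·V_eq.
    """
    fit = surface.isotherm_fit(t)
    v_eq = pressure_volume(fit, p)
    g_cell = float(eval_murnaghan(fit, v_eq)) + p * v_eq * GPA_A3_TO_KJMOL
    return {"v_eq": v_eq, "g": g_cell, "fit": fit}


def thermo_properties(
    surface: FreeEnergySurface,
    temperatures,
    p: float = 0.0,
    z_molecules: int = 1,
    dt: float = 1.0,
) -> ThermoTable:
    """Full state/response property table on a temperature grid.

    S and C_v come from the analytic oscillator formulas at (T, V_eq(T));
    H = G + T·S; C_p = dH/dT and α_p = (1/V)·dV/dT by central differences
    with step ``dt``; κ_T = 1/B(V_eq) from the refitted isotherm.  All
    molar quantities are per molecule (per-cell values divided by Z).
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size > 1 and np.any(np.diff(temperatures) > 10.0 + 1e-9):
        warnings.warn(
            "temperature grid spacing above 10 K; derivative columns may be "
            "unstable, a spacing of 5 K or less is recommended",
            stacklevel=2,
        )

    def state(t):
        st = equilibrium_state(surface, t, p)
        s_cell = vibrational_entropy(surface.freqs_of_v(st["v_eq"]), t)
        h_cell = st["g"] + t * s_cell / 1000.0
        return st["v_eq"], st["g"], h_cell, s_cell, st["fit"]

    n = temperatures.size
    v_eq = np.empty(n)
    g = np.empty(n)
    h = np.empty(n)
    s = np.empty(n)
    cp = np.empty(n)
    cv = np.empty(n)
    alpha = np.empty(n)
    kappa = np.empty(n)

    for i, t in enumerate(temperatures):
        t = float(t)
        v_i, g_i, h_i, s_i, fit_i = state(t)
        v_eq[i], g[i], h[i], s[i] = v_i, g_i, h_i, s_i
        cv[i] = vibrational_cv(surface.freqs_of_v(v_i), t)
        kappa[i] = 1.0 / bulk_modulus(fit_i, v_i)
        if t == 0.0:
            # third law: no thermal population at absolute zero
            cp[i] = 0.0
            alpha[i] = 0.0
            continue
        # shrink the stencil where C_p(T) is strongly curved (low T), so
        # truncation error cannot push C_p below C_v
        dt_eff = min(dt, max(t / 40.0, 0.01))
        lo = max(t - dt_eff, 0.0)
        hi = t + dt_eff
        v_lo, _, h_lo, _, _ = state(lo)
        v_hi, _, h_hi, _, _ = state(hi)
        cp[i] = max((h_hi - h_lo) / (hi - lo) * 1000.0, 0.0)
        alpha[i] = (v_hi - v_lo) / (hi - lo) / v_i

    v0_state = equilibrium_state(surface, 0.0, p)
    zpe_cell = zero_point_energy(surface.freqs_of_v(v0_state["v_eq"]))

    z = z_molecules
    return ThermoTable(
        pressure=p,
        temperatures=temperatures,
        v_eq=v_eq,
        g=g / z,
        h=h / z,
        s=s / z,
        cp=cp / z,
        cv=cv / z,
        alpha_p=alpha,
        kappa_t=kappa,
        zpe=zpe_cell / z,
        z_molecules=z,
    )


def composite_thermo(model, temperatures, p: float = 0.0, volumes=None) -> ThermoTable:
    """Convenience wrapper: surface + property table for a CompositeModel."""
    if volumes is None:
        volumes = model.default_volumes
    surf = build_surface(model.e_of_v, model.freqs_of_v, volumes, temperatures)
    return thermo_properties(surf, temperatures, p, model.z_molecules)


def linear_expansion(cell_params, v_of_t, t1: float, t2: float) -> dict:
    """Per-axis relative expansion between two temperatures.

    ``cell_params`` is a DataFrame with a ``volume`` column and one column
    per lattice parameter (from constrained-volume optimizations that let
    the three lattice vectors vary independently); ``v_of_t`` maps T → V_eq.
    Axis parameters are interpolated linearly in volume, with a warning
    when V_eq leaves the tabulated range.  Returns the per-axis expansions
    a_i(V(T2))/a_i(V(T1)) − 1 plus their min/max (the anisotropy span).
    """
    vol = np.asarray(cell_params["volume"], dtype=float)
    order = np.argsort(vol)
    vol = vol[order]
    axes = [c for c in cell_params.columns if c != "volume"]
    if not axes:
        raise InputError("cell parameter table has no axis columns")

    v1 = float(v_of_t(t1)) if callable(v_of_t) else float(v_of_t[t1])
    v2 = float(v_of_t(t2)) if callable(v_of_t) else float(v_of_t[t2])
    for v in (v1, v2):
        if v < vol[0] or v > vol[-1]:
            warnings.warn(
                f"equilibrium volume {v:.2f} Å³ outside the lattice-parameter "
                "table; linearly extrapolating",
                stacklevel=2,
            )

    out = {}
    for ax in axes:
        y = np.asarray(cell_params[ax], dtype=float)[order]
        a1 = _interp_extrap(vol, y, v1)
        a2 = _interp_extrap(vol, y, v2)
        out[ax] = a2 / a1 - 1.0
    vals = np.array(list(out.values()))
    out["min_axis"] = float(vals.min())
    out["max_axis"] = float(vals.max())
    return out


def _interp_extrap(x: np.ndarray, y: np.ndarray, xq: float) -> float:
    if xq <= x[0]:
        i = 0
    elif xq >= x[-1]:
        i = x.size - 2
    else:
        return float(np.interp(xq, x, y))
    slope = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
    return float(y[i] + slope * (xq - x[i]))
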