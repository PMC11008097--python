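"""The Shift transform and assembly of the composite models M1–M7.

A cheap level of theory (e.g. tight binding, "low") supplies volume
*trends* — the E_el(V) curve shape and the volume dependence of the
phonons — while a costly level ("high", e.g. a converged plane-wave DFT
calculation) anchors them at a single volume:

* **Shift** (M2, M4): the low-level E_el(V) curve is translated
  horizontally by ΔV0 = V0_high − V0_low so its minimum lands on the
  high-level equilibrium volume, E^shift(V) = E^low(V − ΔV0).  Only one
  high-level cell optimization is needed.
* **Extra** (M3, M4): mode Grüneisen parameters fitted to the low-level
  phonons extrapolate the high-level frequencies, computed at a single
  volume, across the whole volume window.
* M5/M6 are the direct cross-combinations of raw ingredients, and
  M1/M7 the pure low/high baselines.

``assemble_composite`` returns the two quasi-harmonic ingredient
functions, E(V) and frequencies(V), for any of the seven models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d

from .datamodel import (
    CompositeSpec,
    EVCurve,
    FrequencySet,
    MurnaghanFit,
    PhononSet,
)
from .eos import eval_murnaghan, fit_murnaghan
from .exceptions import InputError
from .gruneisen import (
    extrapolate_frequencies,
    filter_ranks,
    fit_gruneisen,
    match_modes,
)

__all__ = ["Ingredients", "CompositeModel", "compute_shift", "shift_curve",
           "assemble_composite"]


def compute_shift(fit_low: MurnaghanFit, fit_high: MurnaghanFit) -> float:
    """Horizontal shift ΔV0 = V0_high − V0_low (Å³).

    Positive when the cheap level overbinds (its minimum at lower volume).
    """
    return fit_high.v0 - fit_low.v0


def shift_curve(curve_low: EVCurve, delta_v0: float) -> EVCurve:
    """Translate an E(V) curve horizontally by ΔV0; energies unchanged."""
    return curve_low.shifted(delta_v0)


@dataclass(frozen=True)
class Ingredients:
    """One level's quasi-harmonic inputs.

    For the costly level of the Shift models (M2/M4) a full E(V) curve is
    not required: ``v0`` (and optionally ``e0``) from a single cell
    optimization suffices.
    """

    ev: EVCurve | None = None
    phonons: PhononSet | None = None
    v0: float | None = None    # Å³, single-optimization minimum (Shift anchor)
    e0: float | None = None    # kJ mol⁻¹ per cell at the minimum (optional)


def _is_gamma_flags(phonons: PhononSet) -> list[bool]:
    """Γ flags per q-point; an unlabeled first q-point is taken as Γ."""
    qs = phonons.qpoints[0]
    if all(q.q is None for q in qs):
        return [i == 0 for i in range(len(qs))]
    return [q.is_gamma for q in qs]


class _InterpFreqs:
    """Per-rank log-log interpolation of a volume-resolved phonon set.

    Exact at the sampled volumes; linear in (ln V, ln ν) between them and
    extrapolated with the edge slopes outside the window (a locally
    power-law continuation).
    """

    def __init__(self, phonons: PhononSet):
        self.weights = [q.weight for q in phonons.qpoints[0]]
        flags = _is_gamma_flags(phonons)
        matched = match_modes(phonons)
        self._interp = []
        lx = np.log(phonons.volumes)
        for block, is_g in zip(matched, flags):
            kept = filter_ranks(block, is_g)
            if phonons.volumes.size == 1:
                self._interp.append(kept[:, 0])
            else:
                self._interp.append(
                    interp1d(lx, np.log(kept), axis=1,
                             fill_value="extrapolate", assume_sorted=True)
                )

    def __call__(self, v: float) -> FrequencySet:
        out = []
        for w, itp in zip(self.weights, self._interp):
            if isinstance(itp, np.ndarray):
                out.append((w, itp.copy()))
            else:
                out.append((w, np.exp(itp(np.log(v)))))
        return tuple(out)


class _ExtrapFreqs:
    """Grüneisen extrapolation of single-volume high-level frequencies."""

    def __init__(self, low_phonons: PhononSet, high_phonons: PhononSet,
                 v_ref_target: float | None):
        flags = _is_gamma_flags(low_phonons)
        if low_phonons.volumes.size < 3:
            raise InputError(
                "spec/ingredient mismatch: Grüneisen extrapolation needs the "
                "cheap level's phonons at >= 3 volumes"
            )
        # reference block of the costly level: the volume nearest the target
        vols = high_phonons.volumes
        k = 0 if v_ref_target is None else int(np.argmin(np.abs(vols - v_ref_target)))
        v_ref = float(vols[k])
        high_flags = _is_gamma_flags(high_phonons)
        ref_freqs = []
        for iq, q in enumerate(high_phonons.qpoints[k]):
            block = np.sort(q.frequencies, kind="stable")[:, None]
            ref_freqs.append(filter_ranks(block, high_flags[iq])[:, 0])
        matched = [filter_ranks(b, g)
                   for b, g in zip(match_modes(low_phonons), flags)]
        for iq, (m, r) in enumerate(zip(matched, ref_freqs)):
            if m.shape[0] != r.size:
                raise InputError(
                    "rank alignment failure: cheap and costly phonon sets "
                    f"disagree in mode count at q-point {iq}"
                )
        self.table = fit_gruneisen(matched, low_phonons.volumes, v_ref)
        self.ref_freqs = ref_freqs
        self.v_ref = v_ref
        self.weights = [q.weight for q in high_phonons.qpoints[0]]

    def __call__(self, v: float) -> FrequencySet:
        freqs = extrapolate_frequencies(self.ref_freqs, self.table, v, self.v_ref)
        return tuple(zip(self.weights, freqs))


@dataclass(frozen=True)
class CompositeModel:
    """Assembled quasi-harmonic ingredient functions of one composite model."""

    spec: CompositeSpec
    e_of_v: "callable"
    freqs_of_v: "callable"
    z_molecules: int
    v0_static: float             # minimum volume of e_of_v, Å³
    default_volumes: np.ndarray  # sensible volume grid for F(T, V) surfaces
    delta_v0: float = 0.0        # Shift applied to the static curve, Å³
    static_fit: MurnaghanFit | None = None
    gruneisen_table: object | None = field(default=None, repr=False)


def assemble_composite(
    spec: CompositeSpec | str,
    low: Ingredients,
    high: Ingredients,
    anchor_e0: bool = False,
) -> CompositeModel:
    """Build E(V) and frequencies(V) callables per the composite matrix.

    ``anchor_e0`` additionally re-anchors a shifted static curve's minimum
    energy to the costly level's ``e0`` (off by default: the Shift is a
    horizontal translation only).
    """
    if isinstance(spec, str):
        spec = CompositeSpec.from_model_id(spec)

    # ---- static ingredient -------------------------------------------------
    fit_low = fit_murnaghan(low.ev) if low.ev is not None else None
    fit_high = (fit_murnaghan(high.ev)
                if high.ev is not None and high.ev.volumes.size >= 5 else None)

    delta = 0.0
    if spec.e_source == "raw_low":
        if fit_low is None:
            raise InputError("spec/ingredient mismatch: low-level E(V) curve missing")
        static_fit = fit_low

        def e_of_v(v, _f=fit_low):
            return eval_murnaghan(_f, v)

        v0_static = fit_low.v0
    elif spec.e_source == "raw_high":
        if fit_high is None:
            raise InputError("spec/ingredient mismatch: high-level E(V) curve missing")
        static_fit = fit_high

        def e_of_v(v, _f=fit_high):
            return eval_murnaghan(_f, v)

        v0_static = fit_high.v0
    elif spec.e_source == "shifted_low":
        if fit_low is None:
            raise InputError("spec/ingredient mismatch: low-level E(V) curve missing")
        v0_high = fit_high.v0 if fit_high is not None else high.v0
        if v0_high is None:
            raise InputError(
                "spec/ingredient mismatch: Shift needs the high-level minimum "
                "volume (full E(V) curve or a single-optimization v0)"
            )
        delta = v0_high - fit_low.v0
        offset = 0.0
        if anchor_e0:
            e0_high = fit_high.e0 if fit_high is not None else high.e0
            if e0_high is None:
                raise InputError(
                    "spec/ingredient mismatch: anchor_e0 needs the high-level e0"
                )
            offset = e0_high - fit_low.e0
        static_fit = fit_low

        def e_of_v(v, _f=fit_low, _d=delta, _o=offset):
            return eval_murnaghan(_f, np.asarray(v) - _d) + _o

        v0_static = fit_low.v0 + delta
    else:  # pragma: no cover - guarded by CompositeSpec
        raise InputError(f"unknown e_source {spec.e_source!r}")

    # ---- dynamic ingredient ------------------------------------------------
    gru_table = None
    if spec.phonon_source == "raw_low":
        if low.phonons is None:
            raise InputError("spec/ingredient mismatch: low-level phonons missing")
        freqs_of_v = _InterpFreqs(low.phonons)
        basis_volumes = low.phonons.volumes
    elif spec.phonon_source == "raw_high":
        if high.phonons is None:
            raise InputError("spec/ingredient mismatch: high-level phonons missing")
        freqs_of_v = _InterpFreqs(high.phonons)
        basis_volumes = (high.phonons.volumes if high.phonons.volumes.size > 1
                         else (low.ev.volumes if low.ev is not None
                               else high.ev.volumes))
    elif spec.phonon_source == "extrapolated_high":
        if high.phonons is None:
            raise InputError(
                "spec/ingredient mismatch: single-volume high-level phonons missing"
            )
        if low.phonons is None:
            raise InputError("spec/ingredient mismatch: low-level phonons missing")
        target = fit_high.v0 if fit_high is not None else high.v0
        extrap = _ExtrapFreqs(low.phonons, high.phonons, target)
        freqs_of_v = extrap
        gru_table = extrap.table
        basis_volumes = low.phonons.volumes
    else:  # pragma: no cover
        raise InputError(f"unknown phonon_source {spec.phonon_source!r}")

    # shift the default surface grid with the static curve so the new
    # minimum stays bracketed (off-window A_vib comes from extrapolation)
    default_volumes = np.asarray(basis_volumes, dtype=float) + delta

    z_values = {c.z_molecules for c in (low.ev, high.ev) if c is not None}
    if len(z_values) > 1:
        raise InputError(f"inconsistent Z between ingredient curves: {z_values}")
    z = z_values.pop() if z_values else 1

    return CompositeModel(
        spec=spec,
        e_of_v=e_of_v,
        freqs_of_v=freqs_of_v,
        z_molecules=z,
        v0_static=float(v0_static),
        default_volumes=default_volumes,
        delta_v0=float(delta),
        static_fit=static_fit,
        gruneisen_table=gru_table,
    )
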