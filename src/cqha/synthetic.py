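"""Analytic model crystals for testing every pipeline stage.

The generator emulates the cheap/costly ("low"/"high") ingredient pair
of the composite workflow with fully analytic physics: static energies
are exactly Murnaghan and every phonon mode follows the exact power law
ν(V) = ν⁰·(V/V0)^(−γ).  Defaults mirror a small-molecule pharmaceutical
crystal: Z = 4, ~50 optical modes from 0.5 THz lattice vibrations to
95 THz C–H stretches, a 9% volume offset between the levels' minima and
a ~50% curvature difference.  Closed-form oscillator sums and an exact
free-energy minimizer serve as independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import R_GAS, THZ_TO_K, THZ_TO_KJMOL
from .datamodel import CrystalStructure, EVCurve, PhononSet, QPoint
from .eos import murnaghan_energy
from .exceptions import InputError
from .molecules import perceive_molecules

__all__ = [
    "LevelSpec",
    "ModelCrystalSpec",
    "default_mode_table",
    "make_model_crystal",
    "oracle_thermo",
    "oracle_gibbs",
    "make_toy_lattice",
    "lennard_jones",
]


def default_mode_table(n_modes: int = 48) -> np.ndarray:
    """Reference optical-mode table: rows of (ν⁰ THz, γ).

    Frequencies are log-spaced from lattice modes (0.5 THz) to C–H
    stretches (95 THz); Grüneisen parameters decay from ~3 for the soft
    lattice modes to near zero for the stiff intramolecular ones, the
    hierarchy that drives thermal expansion in molecular crystals.
    """
    nu0 = np.geomspace(0.5, 95.0, n_modes)
    gamma = 0.03 + 3.3 * np.exp(-nu0 / 12.0)
    return np.stack([nu0, gamma], axis=1)


@dataclass(frozen=True)
class LevelSpec:
    """Analytic ingredients of one level of theory."""

    v0: float                 # Å³ per cell
    b0: float                 # GPa
    b0_prime: float           # dimensionless
    e0: float                 # kJ mol⁻¹ per cell
    modes: np.ndarray         # (n, 2) rows of (nu0 THz at v0, gamma)

    def __post_init__(self) -> None:
        m = np.asarray(self.modes, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "modes", m)
        if np.any(m[:, 0] <= 0):
            raise InputError("mode frequencies must be positive")

    def frequencies(self, v: float) -> np.ndarray:
        """Exact mode frequencies at volume v (THz)."""
        return self.modes[:, 0] * (v / self.v0) ** (-self.modes[:, 1])

    def energy(self, v) -> np.ndarray:
        return murnaghan_energy(v, self.e0, self.v0, self.b0, self.b0_prime)


@dataclass(frozen=True)
class ModelCrystalSpec:
    """A matched low/high model-crystal pair.

    Defaults encode the study conditions: the cheap level's minimum sits
    at 91% of the costly one's (an 8–10% overbinding shift) with a ~50%
    stiffer curvature; mode tables coincide (the similar-slope regime
    that justifies Grüneisen transfer).  ``noise_sd`` adds seeded
    multiplicative noise to the generated frequencies.
    """

    v0_high: float = 920.0
    v0_low: float = field(default=0.0)   # 0 → 0.91·v0_high
    b0_high: float = 10.0
    b0_low: float = 15.0
    b0_prime: float = 5.0
    e0_high: float = 0.0
    e0_low: float = 0.0
    mode_table_high: np.ndarray | None = None
    mode_table_low: np.ndarray | None = None
    z_molecules: int = 4
    n_qpoints: int = 1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v0_low == 0.0:
            object.__setattr__(self, "v0_low", 0.91 * self.v0_high)
        if self.mode_table_high is None:
            object.__setattr__(self, "mode_table_high", default_mode_table())
        if self.mode_table_low is None:
            object.__setattr__(self, "mode_table_low",
                               np.array(self.mode_table_high, copy=True))
        if self.n_qpoints not in (1, 2):
            raise InputError("n_qpoints must be 1 or 2")

    @property
    def high(self) -> LevelSpec:
        return LevelSpec(self.v0_high, self.b0_high, self.b0_prime,
                         self.e0_high, self.mode_table_high)

    @property
    def low(self) -> LevelSpec:
        return LevelSpec(self.v0_low, self.b0_low, self.b0_prime,
                         self.e0_low, self.mode_table_low)


@dataclass(frozen=True)
class SyntheticCrystal:
    """Generated ingredient set of one model crystal."""

    spec: ModelCrystalSpec
    ev_low: EVCurve
    ev_high: EVCurve
    phonons_low: PhononSet
    phonons_high: PhononSet          # full volume-resolved set
    phonons_high_single: PhononSet   # single block at v0_high (Shift/Extra input)


def _qpoint_blocks(level: LevelSpec, v: float, n_qpoints: int,
                   rng: np.random.Generator | None, noise_sd: float):
    """Q-point records at one volume: Γ (with 3 zero acoustic modes) and
    optionally one off-Γ point with finite acoustic branches."""
    optical = level.frequencies(v)
    if rng is not None and noise_sd > 0:
        optical = optical * (1.0 + noise_sd * rng.standard_normal(optical.size))
    blocks = []
    if n_qpoints == 1:
        freqs = np.concatenate([[0.0, 0.0, 0.0], optical])
        blocks.append(QPoint(1.0, freqs, q=(0.0, 0.0, 0.0)))
    else:
        freqs_g = np.concatenate([[0.0, 0.0, 0.0], optical])
        blocks.append(QPoint(0.25, freqs_g, q=(0.0, 0.0, 0.0)))
        acoustic = np.array([0.45, 0.55, 0.65]) * (v / level.v0) ** (-2.0)
        freqs_x = np.concatenate([acoustic, optical * 1.02])
        blocks.append(QPoint(0.75, freqs_x, q=(0.5, 0.0, 0.0)))
    return tuple(blocks)


def make_model_crystal(
    spec: ModelCrystalSpec,
    span: float = 0.10,
    n_volumes: int = 7,
) -> SyntheticCrystal:
    """Generate the four quasi-harmonic ingredients of a model crystal.

    Each level is sampled on ``n_volumes`` points spanning ±``span``
    around its own minimum, so both minima are bracketed by construction.
    Energies are exactly Murnaghan; frequencies exactly power-law, with
    optional seeded multiplicative noise.
    """
    if n_volumes < 5:
        raise InputError("insufficient points: need >= 5 volumes per curve")
    if span <= 0:
        raise InputError("volume span must be positive")
    rng = np.random.default_rng(spec.seed) if spec.noise_sd > 0 else None

    def grid(v0):
        return v0 * np.linspace(1.0 - span, 1.0 + span, n_volumes)

    v_low, v_high = grid(spec.v0_low), grid(spec.v0_high)
    ev_low = EVCurve(v_low, spec.low.energy(v_low), "low", spec.z_molecules)
    ev_high = EVCurve(v_high, spec.high.energy(v_high), "high", spec.z_molecules)

    def phonons(level, vols, label):
        return PhononSet(
            vols,
            tuple(_qpoint_blocks(level, v, spec.n_qpoints, rng, spec.noise_sd)
                  for v in vols),
            label,
        )

    ph_low = phonons(spec.low, v_low, "low")
    ph_high = phonons(spec.high, v_high, "high")
    ph_high_single = PhononSet(
        np.array([spec.v0_high]),
        (_qpoint_blocks(spec.high, spec.v0_high, spec.n_qpoints, rng,
                        spec.noise_sd),),
        "high",
    )
    return SyntheticCrystal(spec, ev_low, ev_high, ph_low, ph_high, ph_high_single)


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------

def oracle_thermo(level: LevelSpec, t: float, v: float) -> dict:
    """Exact oscillator sums at (T, V): a_vib, s, cv per cell.

    Independent of the pipeline: evaluates the closed-form Bose-Einstein
    expressions directly on the level's analytic optical frequencies
    (Γ-only convention).  Units kJ mol⁻¹ / J K⁻¹ mol⁻¹ per cell.
    """
    if t < 0:
        raise InputError("temperature must be nonnegative")
    nu = level.frequencies(v)
    zpe = 0.5 * THZ_TO_KJMOL * float(np.sum(nu))
    if t == 0:
        return {"a_vib": zpe, "s": 0.0, "cv": 0.0}
    x = THZ_TO_K * nu / t
    a = zpe + R_GAS * t * float(np.sum(np.log1p(-np.exp(-x)))) / 1000.0
    s = R_GAS * float(np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))
    cv = R_GAS * float(np.sum((0.5 * x / np.sinh(0.5 * x)) ** 2))
    return {"a_vib": a, "s": s, "cv": cv}


def oracle_gibbs(level: LevelSpec, t: float, p: float = 0.0) -> dict:
    """Exact G(T, p) per cell by direct minimization of E + A_vib + pV."""
    from .constants import GPA_A3_TO_KJMOL

    def f(v):
        return (float(level.energy(v)) + oracle_thermo(level, t, v)["a_vib"]
                + p * v * GPA_A3_TO_KJMOL)

    res = minimize_scalar(
        f, bounds=(0.6 * level.v0, 1.5 * level.v0), method="bounded",
        options={"xatol": 1e-10},
    )
    return {"v_eq": float(res.x), "g": float(res.fun)}


# ---------------------------------------------------------------------------
# toy lattices for the fragment module
# ---------------------------------------------------------------------------

def lennard_jones(epsilon: float = 1.0, sigma: float = 3.4):
    """Element-independent 12-6 potential, ε in kJ mol⁻¹, σ in Å."""

    def pot(_ea: str, _eb: str, r: float) -> float:
        sr6 = (sigma / r) ** 6
        return 4.0 * epsilon * (sr6 * sr6 - sr6)

    return pot


def make_toy_lattice(kind: str, a: float = 5.0):
    """Small analytic crystals exercising the dimer machinery.

    Returns ``(structure, pair_potential)`` where the structure carries a
    molecule partition and the potential feeds
    :func:`cqha.fragments.evaluate_pair_energies`.
    """
    if a <= 0:
        raise InputError("lattice constant must be positive")
    if kind == "cubic_1mol":
        cell = np.eye(3) * a
        elements = ("Ar",)
        frac = np.array([[0.0, 0.0, 0.0]])
    elif kind == "cubic_2mol":
        cell = np.eye(3) * a
        elements = ("Ar", "Kr")
        frac = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]])
    elif kind == "triclinic_2mol":
        cell = np.array([
            [a, 0.0, 0.0],
            [0.35 * a, 1.05 * a, 0.0],
            [0.20 * a, 0.15 * a, 0.95 * a],
        ])
        elements = ("Ar", "Kr")
        frac = np.array([[0.05, 0.1, 0.0], [0.55, 0.5, 0.45]])
    else:
        raise InputError(f"unknown toy lattice kind {kind!r}")
    struct = CrystalStructure(cell, elements, frac)
    struct = perceive_molecules(struct, bond_margin=-10.0)  # all single atoms
    return struct, lennard_jones(epsilon=1.0, sigma=0.68 * a)


def oracle_manifest(spec: ModelCrystalSpec, temperatures) -> dict:
    """High-level oracle G(T) written next to generated ingredient files."""
    return {
        "temperatures": list(map(float, temperatures)),
        "g_high_per_cell": [oracle_gibbs(spec.high, float(t))["g"]
                            for t in temperatures],
        "z_molecules": spec.z_molecules,
    }
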