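"""Shared domain types.

All quantities are stored in the package's internal units: Å³ and
kJ mol⁻¹ per unit cell, THz, K, GPa.  Per-molecule reporting divides
per-cell quantities by ``z_molecules`` (the crystallographic Z).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "EVCurve",
    "MurnaghanFit",
    "QPoint",
    "PhononSet",
    "FrequencySet",
    "ModeFit",
    "GruneisenTable",
    "CompositeSpec",
    "COMPOSITE_MATRIX",
    "ThermoTable",
    "CrystalStructure",
    "DimerRecord",
]


@dataclass(frozen=True)
class EVCurve:
    """Static electronic energy sampled on a volume grid.

    The E_el(V) curve is the static ingredient of the quasi-harmonic
    approximation: unit cells relaxed at a series of constrained volumes.

    Attributes
    ----------
    volumes : ndarray
        Cell volumes, Å³, strictly increasing.
    energies : ndarray
        Electronic energies, kJ mol⁻¹ per cell.
    level_label : str
        Level of theory that produced the curve (e.g. ``"DFTB"``, ``"PBE"``).
    z_molecules : int
        Molecules per unit cell (Z).
    """

    volumes: np.ndarray
    energies: np.ndarray
    level_label: str = ""
    z_molecules: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "energies", e)
        if v.ndim != 1 or e.shape != v.shape:
            raise InputError("volumes and energies must be matching 1-D arrays")
        if v.size < 5:
            raise InputError("insufficient points: E(V) curve needs >= 5 samples")
        if np.any(v <= 0):
            raise InputError("volumes must be positive")
        if np.any(np.diff(v) == 0):
            raise InputError("duplicate volume in E(V) curve")
        if np.any(np.diff(v) < 0):
            raise InputError("volumes must be strictly increasing")
        if self.z_molecules < 1:
            raise InputError("z_molecules must be a positive integer")

    @property
    def has_interior_minimum(self) -> bool:
        """True when the lowest sampled energy is not at an endpoint."""
        i = int(np.argmin(self.energies))
        return 0 < i < self.energies.size - 1

    def shifted(self, delta_v: float) -> "EVCurve":
        """Curve translated horizontally by ``delta_v`` Å³ (energies kept)."""
        return replace(self, volumes=self.volumes + delta_v)


@dataclass(frozen=True)
class MurnaghanFit:
    """Murnaghan equation-of-state parameters of an E(V) curve.

    E(V) = E0 + B0·V/B0′·[(V0/V)^B0′/(B0′−1) + 1] − B0·V0/(B0′−1),
    with B0 converted from GPa to kJ mol⁻¹ Å⁻³ for evaluation.
    """

    e0: float          # kJ mol⁻¹ per cell
    v0: float          # Å³ per cell
    b0: float          # GPa
    b0_prime: float    # dimensionless, > 1
    rms_residual: float = 0.0  # kJ mol⁻¹

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise InputError("v0 must be positive")
        if self.b0 <= 0:
            raise InputError("b0 must be positive")
        if self.b0_prime <= 1:
            raise InputError("b0_prime must exceed 1 (Murnaghan singular at 1)")
        if self.rms_residual < 0:
            raise InputError("rms_residual must be nonnegative")


@dataclass(frozen=True)
class QPoint:
    """One Brillouin-zone sampling point: weight and mode frequencies.

    Frequencies are THz; a negative value encodes an imaginary mode.
    ``q`` is the fractional coordinate of the point when known; the
    Γ point is identified by ``q == (0, 0, 0)``.
    """

    weight: float
    frequencies: np.ndarray
    q: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frequencies", np.asarray(self.frequencies, dtype=float)
        )
        if self.weight <= 0:
            raise InputError("q-point weight must be positive")

    @property
    def is_gamma(self) -> bool:
        return self.q is not None and all(abs(c) < 1e-12 for c in self.q)


@dataclass(frozen=True)
class PhononSet:
    """Per-volume phonon frequencies on a common q-point mesh.

    ``qpoints[k]`` is the list of :class:`QPoint` records for volume
    ``volumes[k]``.  Every volume must carry the same q-point list
    (weights, coordinates) and the same mode count per q-point.
    """

    volumes: np.ndarray
    qpoints: tuple[tuple[QPoint, ...], ...]
    level_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(
            self, "qpoints", tuple(tuple(qs) for qs in self.qpoints)
        )
        if v.ndim != 1 or v.size == 0 or np.any(v <= 0):
            raise InputError("phonon volumes must be positive")
        if len(self.qpoints) != v.size:
            raise InputError("one q-point block required per volume")
        ref = self.qpoints[0]
        for block in self.qpoints[1:]:
            if len(block) != len(ref):
                raise InputError("ragged phonon set: q-point count differs")
            for qa, qb in zip(ref, block):
                if qa.frequencies.size != qb.frequencies.size:
                    raise InputError(
                        "ragged phonon set: mode count differs across volumes"
                    )
                if abs(qa.weight - qb.weight) > 1e-10:
                    raise InputError("q-point weights differ across volumes")
        wsum = sum(q.weight for q in ref)
        if abs(wsum - 1.0) > 1e-10:
            raise InputError(f"bad weights: q-point weights sum to {wsum!r}")

    @property
    def n_qpoints(self) -> int:
        return len(self.qpoints[0])

    @property
    def n_modes(self) -> tuple[int, ...]:
        return tuple(q.frequencies.size for q in self.qpoints[0])


#: A single-volume set of weighted frequencies, as consumed by the
#: harmonic-oscillator thermodynamics: sequence of (weight, frequencies)
#: with all frequencies positive (acoustic/imaginary modes filtered out).
FrequencySet = Sequence[tuple[float, np.ndarray]]


@dataclass(frozen=True)
class ModeFit:
    """Power-law frequency/volume fit of one mode rank: ν(V) = ν⁰·(V/V_ref)^(−γ)."""

    nu0: float           # THz at v_ref
    gamma: float         # mode Grüneisen parameter, dimensionless
    fit_residual: float  # rms deviation, THz

    def __post_init__(self) -> None:
        if self.nu0 <= 0:
            raise InputError("nu0 must be positive")
        if self.fit_residual < 0:
            raise InputError("fit_residual must be nonnegative")


@dataclass(frozen=True)
class GruneisenTable:
    """Per-q-point, per-rank mode Grüneisen parameters about a reference volume."""

    v_ref: float                               # Å³ per cell
    modes: tuple[tuple[ModeFit, ...], ...]     # [q-point][rank]

    def __post_init__(self) -> None:
        if self.v_ref <= 0:
            raise InputError("v_ref must be positive")
        object.__setattr__(self, "modes", tuple(tuple(m) for m in self.modes))

    def gammas(self, iq: int) -> np.ndarray:
        return np.array([m.gamma for m in self.modes[iq]])

    def nu0s(self, iq: int) -> np.ndarray:
        return np.array([m.nu0 for m in self.modes[iq]])


#: The fixed composite-model matrix: model id → (static source, phonon source).
#: M1 is the all-cheap baseline, M7 the all-costly reference; M2 shifts the
#: cheap E(V) onto the costly minimum, M3 Grüneisen-extrapolates the costly
#: phonons with cheap γ's, M4 does both, M5/M6 are the direct cross-combinations.
COMPOSITE_MATRIX: dict[str, tuple[str, str]] = {
    "M1": ("raw_low", "raw_low"),
    "M2": ("shifted_low", "raw_low"),
    "M3": ("raw_low", "extrapolated_high"),
    "M4": ("shifted_low", "extrapolated_high"),
    "M5": ("raw_high", "raw_low"),
    "M6": ("raw_low", "raw_high"),
    "M7": ("raw_high", "raw_high"),
}


@dataclass(frozen=True)
class CompositeSpec:
    """Which level of theory supplies each quasi-harmonic ingredient."""

    model_id: str
    e_source: str
    phonon_source: str

    def __post_init__(self) -> None:
        if self.model_id not in COMPOSITE_MATRIX:
            raise InputError(f"unknown composite model {self.model_id!r}")
        if COMPOSITE_MATRIX[self.model_id] != (self.e_source, self.phonon_source):
            raise InputError(
                f"source pair {(self.e_source, self.phonon_source)!r} does not "
                f"match the fixed matrix entry for {self.model_id}"
            )

    @classmethod
    def from_model_id(cls, model_id: str) -> "CompositeSpec":
        model_id = model_id.upper()
        if model_id not in COMPOSITE_MATRIX:
            raise InputError(f"unknown composite model {model_id!r}")
        e_src, ph_src = COMPOSITE_MATRIX[model_id]
        return cls(model_id, e_src, ph_src)


_THERMO_COLUMNS = ("v_eq", "g", "h", "s", "cp", "cv", "alpha_p", "kappa_t")


@dataclass(frozen=True)
class ThermoTable:
    """State and response properties on a temperature grid at one pressure.

    Units: g, h in kJ mol⁻¹ per molecule; s, cp, cv in J K⁻¹ mol⁻¹ per
    molecule; v_eq in Å³ per cell; alpha_p in K⁻¹; kappa_t in GPa⁻¹;
    zpe in kJ mol⁻¹ per molecule.
    """

    pressure: float
    temperatures: np.ndarray
    v_eq: np.ndarray
    g: np.ndarray
    h: np.ndarray
    s: np.ndarray
    cp: np.ndarray
    cv: np.ndarray
    alpha_p: np.ndarray
    kappa_t: np.ndarray
    zpe: float
    z_molecules: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "temperatures", t)
        if t.size == 0:
            raise InputError("nothing to write: empty temperature grid")
        if np.any(np.diff(t) <= 0):
            raise InputError("temperatures must be strictly increasing")
        if self.pressure < 0:
            raise InputError("pressure must be nonnegative")
        for name in _THERMO_COLUMNS:
            col = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, col)
            if col.shape != t.shape:
                raise InputError(f"column {name} does not match temperature grid")

    def to_frame(self) -> pd.DataFrame:
        data = {"temperature": self.temperatures}
        data.update({name: getattr(self, name) for name in _THERMO_COLUMNS})
        return pd.DataFrame(data)

    def replace(self, **kwargs) -> "ThermoTable":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CrystalStructure:
    """Periodic crystal with a molecule partition.

    ``cell_vectors`` rows are the lattice vectors in Å; ``frac_coords``
    are wrapped to [0, 1).  ``molecule_partition[k]`` is the molecule
    index of atom ``k``; molecules are connected components under the
    covalent-radius bonding criterion (periodic images included).
    """

    cell_vectors: np.ndarray                  # 3×3, Å, rows = a, b, c
    elements: tuple[str, ...]
    frac_coords: np.ndarray                   # n×3, wrapped to [0, 1)
    molecule_partition: np.ndarray | None = None   # n, int
    symmetry_ops: tuple | None = None         # optional (rot 3×3, trans 3) pairs

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell_vectors, dtype=float).reshape(3, 3)
        frac = np.asarray(self.frac_coords, dtype=float)
        object.__setattr__(self, "cell_vectors", cell)
        object.__setattr__(self, "frac_coords", frac % 1.0)
        object.__setattr__(self, "elements", tuple(self.elements))
        if abs(np.linalg.det(cell)) < 1e-9:
            raise InputError("not a crystal: degenerate cell vectors")
        if frac.shape != (len(self.elements), 3):
            raise InputError("frac_coords must be n_atoms × 3")
        if self.molecule_partition is not None:
            part = np.asarray(self.molecule_partition, dtype=int)
            object.__setattr__(self, "molecule_partition", part)
            if part.shape != (len(self.elements),):
                raise InputError("molecule_partition must cover all atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_molecules(self) -> int:
        if self.molecule_partition is None:
            raise InputError("molecules not perceived")
        return int(self.molecule_partition.max()) + 1

    def cart_coords(self) -> np.ndarray:
        return self.frac_coords @ self.cell_vectors


@dataclass(frozen=True)
class DimerRecord:
    """A symmetry-unique molecular pair with its lattice multiplicity.

    ``translation`` is the integer lattice vector carrying molecule
    ``mol_j`` into the image that realizes the contact; ``multiplicity``
    counts the anchored (ordered) in-cutoff pairs this record represents,
    so Eq-style lattice sums use ½·multiplicity·ε per record.
    """

    mol_i: int
    mol_j: int
    translation: tuple[int, int, int]
    min_distance: float          # Å, closest atom–atom contact
    multiplicity: int
    pair_energy: float | None = None   # kJ mol⁻¹ (ε_ij)

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise InputError("min_distance must be positive")
        if self.multiplicity < 1:
            raise InputError("multiplicity must be >= 1")
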