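"""Mode Grüneisen parameters from sorted-rank mode matching.

Eigenvector-based mode matching is deliberately avoided: at each q-point
the frequencies of every sampled volume are sorted ascending and the
N-th lowest mode of one volume is identified with the N-th lowest of the
others.  Per rank, the volume dependence is fitted with the constant-γ
power law

    ν(V) = ν⁰ · (V / V_ref)^(−γ),

the closed-form solution of γ = −∂ln ν/∂ln V, as a linear least-squares
problem in log–log space.  The resulting γ table extrapolates a costly
level's single-volume frequencies across the whole volume window:

    ν_r(V) = ν_r(V_ref) · (V_ref / V)^(γ_r).
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import GruneisenTable, ModeFit, PhononSet
from .exceptions import InputError, NumericalError

__all__ = [
    "match_modes",
    "filter_ranks",
    "fit_gruneisen",
    "extrapolate_frequencies",
    "ACOUSTIC_TOL_THZ",
    "IMAGINARY_TOL_THZ",
]

#: Γ-point acoustic modes are zero up to numerical noise; modes below this
#: threshold (among the three lowest ranks at Γ) are dropped before fitting.
ACOUSTIC_TOL_THZ = 0.3

#: Imaginary modes smaller in magnitude than this are treated as numerical
#: noise (dropped with a warning); larger imaginary modes abort, since a
#: genuinely unstable structure invalidates the quasi-harmonic picture.
IMAGINARY_TOL_THZ = 0.1


def match_modes(phonons: PhononSet) -> list[np.ndarray]:
    """Rank-match frequencies across volumes by sorted order.

    Returns one array per q-point of shape ``(n_modes, n_volumes)``:
    row ``r`` holds the r-th lowest frequency at every volume.  Negative
    (imaginary) frequencies sort below real ones; degenerate frequencies
    keep a stable order.
    """
    matched = []
    for iq in range(phonons.n_qpoints):
        block = np.stack(
            [np.sort(phonons.qpoints[k][iq].frequencies, kind="stable")
             for k in range(len(phonons.volumes))],
            axis=-1,
        )
        matched.append(block)
    return matched


def filter_ranks(
    matched_q: np.ndarray,
    is_gamma: bool,
    acoustic_tol: float = ACOUSTIC_TOL_THZ,
    imaginary_tol: float = IMAGINARY_TOL_THZ,
) -> np.ndarray:
    """Drop acoustic and noise-level imaginary ranks from a matched block.

    ``matched_q`` is the sorted ``(n_modes, n_volumes)`` array of one
    q-point.  At Γ, up to three of the lowest ranks whose magnitude stays
    below ``acoustic_tol`` at every volume are removed.  Remaining ranks
    containing small imaginary entries (|ν| < ``imaginary_tol``) are
    dropped with a warning; larger imaginary entries raise.
    """
    keep = np.ones(matched_q.shape[0], dtype=bool)
    if is_gamma:
        small = np.max(np.abs(matched_q), axis=1) < acoustic_tol
        for r in range(min(3, matched_q.shape[0])):
            if small[r]:
                keep[r] = False
    for r in np.nonzero(keep)[0]:
        row = matched_q[r]
        if np.any(row <= 0):
            if np.all(np.abs(row[row <= 0]) < imaginary_tol):
                warnings.warn(
                    "dropping near-zero/imaginary mode rank "
                    f"{r} (|ν| < {imaginary_tol} THz)",
                    stacklevel=2,
                )
                keep[r] = False
            else:
                raise NumericalError(
                    "imaginary mode in fit window: structure dynamically unstable"
                )
    return matched_q[keep]


def fit_gruneisen(
    matched: list[np.ndarray], volumes: np.ndarray, v_ref: float
) -> GruneisenTable:
    """Fit ν(V) = ν⁰·(V/V_ref)^(−γ) per q-point and rank.

    ``matched`` is the output of :func:`match_modes` (after filtering);
    all frequencies must be positive.  The fit is linear least squares on
    ln ν = ln ν⁰ − γ·ln(V/V_ref), exact for exact power-law data.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size < 3:
        raise InputError("gruneisen fit needs >= 3 volumes")
    if v_ref <= 0:
        raise InputError("v_ref must be positive")
    x = np.log(volumes / v_ref)
    design = np.stack([np.ones_like(x), -x], axis=-1)
    table = []
    for block in matched:
        if np.any(block <= 0):
            raise NumericalError(
                "imaginary mode in fit window: filter modes before fitting"
            )
        if block.shape[1] != volumes.size:
            raise InputError("matched array does not cover the volume grid")
        coef, *_ = np.linalg.lstsq(design, np.log(block).T, rcond=None)
        nu0 = np.exp(coef[0])
        gamma = coef[1]
        fitted = nu0[None, :] * (volumes[:, None] / v_ref) ** (-gamma[None, :])
        resid = np.sqrt(np.mean((fitted.T - block) ** 2, axis=1))
        table.append(
            tuple(
                ModeFit(float(n), float(g), float(r))
                for n, g, r in zip(nu0, gamma, resid)
            )
        )
    return GruneisenTable(float(v_ref), tuple(table))


def extrapolate_frequencies(
    ref_freqs: list[np.ndarray],
    table: GruneisenTable,
    v: float,
    v_ref_high: float | None = None,
) -> list[np.ndarray]:
    """Scale single-volume reference frequencies to volume ``v``.

    ``ref_freqs`` holds the costly level's frequencies (one sorted array
    per q-point, positive, same rank convention as ``table``) at the
    reference volume ``v_ref_high`` (defaults to ``table.v_ref``).  Rank
    ``r`` is scaled by ``(v_ref_high / v)**γ_r`` with the cheap level's γ.
    """
    if v <= 0:
        raise InputError("volume must be positive")
    vr = table.v_ref if v_ref_high is None else v_ref_high
    if len(ref_freqs) != len(table.modes):
        raise InputError("rank alignment failure: q-point count mismatch")
    out = []
    for iq, freqs in enumerate(ref_freqs):
        freqs = np.sort(np.asarray(freqs, dtype=float), kind="stable")
        if freqs.size != len(table.modes[iq]):
            raise InputError("rank alignment failure: mode count mismatch")
        gammas = table.gammas(iq)
        out.append(freqs * (vr / v) ** gammas)
    return out
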