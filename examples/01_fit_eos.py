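"""Fit the Murnaghan equation of state to an E(V) curve.

Reads a cheap-level (tight-binding) static energy scan shipped with the
package and extracts the equilibrium volume V0, bulk modulus B0 and its
pressure derivative B0', the four numbers that parameterize the static
ingredient of every quasi-harmonic model.
"""

from pathlib import Path

from cqha import fit_murnaghan, read_ev_curve

curve = read_ev_curve(Path(__file__).parent / "data" / "ev_dftb.csv")
fit = fit_murnaghan(curve)

print(f"level label      : {curve.level_label} (Z = {curve.z_molecules})")
print(f"V0  = {fit.v0:10.3f} Å³/cell   (equilibrium volume)")
print(f"B0  = {fit.b0:10.3f} GPa       (bulk modulus: stiffness at V0)")
print(f"B0' = {fit.b0_prime:10.3f}            (pressure derivative of B0)")
print(f"E0  = {fit.e0:10.3f} kJ/mol    (static energy at the minimum)")
print(f"rms = {fit.rms_residual:10.2e} kJ/mol   (fit residual; ~0 means the")
print("      sampled points are Murnaghan-consistent)")
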