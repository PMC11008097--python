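# Methods

## The quasi-harmonic model

A molecular crystal's Helmholtz energy is approximated as

    F(T, V) = E_el(V) + A_vib(T, V),

where `E_el(V)` is the static electronic energy of the cell relaxed at
constrained volume and `A_vib` is the harmonic-oscillator vibrational
free energy of the phonons computed at that volume,

    A_vib(T, V) = Σ_q w_q Σ_i [ N_A·h·ν_i(V)/2 + R·T·ln(1 − e^(−h·ν_i(V)/k_B·T)) ].

Minimizing `F(T, V) + p·V` over volume yields the equilibrium volume
`V_eq(T, p)` and the Gibbs energy; thermal expansion emerges purely from
the volume dependence of the phonon frequencies.  Everything downstream
— entropy, enthalpy, heat capacities, expansivity `α_p`, compressibility
`κ_T`, and polymorph ΔG(T) rankings — follows from this surface.

`E_el(V)` is parameterized with the Murnaghan equation of state
(E0, V0, B0, B0′); per-temperature isotherms `F(V)` are refit with the
same form so that `V_eq`, `G` and the isothermal bulk modulus have
closed forms.  Per-molecule quantities divide per-cell values by the
crystallographic Z.

## Composite models M1–M7

Volume-resolved phonon and cell-relaxation scans are the expensive part
of the workflow.  The composite models reuse a cheap level of theory's
*volume trends* (typically dispersion-corrected tight binding) and
anchor them with a costly level's *single-volume* results (converged
plane-wave DFT):

| model | static E(V)     | phonons                      |
|-------|-----------------|------------------------------|
| M1    | cheap           | cheap                        |
| M2    | cheap, shifted  | cheap                        |
| M3    | cheap           | costly, Grüneisen-extrapolated |
| M4    | cheap, shifted  | costly, Grüneisen-extrapolated |
| M5    | costly          | cheap                        |
| M6    | cheap           | costly (raw)                 |
| M7    | costly          | costly                       |

**Shift (M2/M4).**  Cheap levels overbind molecular crystals; their
E(V) minimum sits ~8–10% below the costly V0.  The transform translates
the whole cheap curve horizontally by ΔV0 = V0_high − V0_low, so the
minimum lands exactly on the costly V0 while the curve *shape* stays the
cheap level's.  The shift is horizontal only; an optional `anchor_e0`
flag re-anchors the minimum energy for cross-polymorph use (off by
default — energy-level corrections are the fragment refinement's job).
The shifted `e_of_v` is the exact translated EOS function
`E_low(V − ΔV0)`, not a refit: a translated Murnaghan is not itself a
Murnaghan, and representing it exactly keeps the minimum at V0_high to
machine precision.

**Extra (M3/M4).**  Per mode, the Grüneisen parameter
γ = −∂ln ν/∂ln V is fitted to the cheap level's volume-resolved
phonons and used to extrapolate the costly level's frequencies from a
single volume: ν_r(V) = ν_r(V_ref)·(V_ref/V)^γ_r.  Mode matching across
volumes is by *rank in the sorted frequency list*, per q-point (not
pooled across q-points: counts per q-point are guaranteed equal and
physical continuity is stronger within one).  Eigenvector-overlap
matching is intentionally out of scope.  The fit is linear least
squares in log–log space — the two-parameter power law is exact for
exact power-law data and convex always.  The reference volume is the
costly phonon calculation's own volume (conventionally its V0).

## Numerical choices

* **EOS fitting.**  Trust-region least squares with an analytic
  Jacobian, initial values from a quadratic pre-fit (vertex → V0,
  curvature → B0, B0′ = 4), B0′ constrained to (1, 20] (the Murnaghan
  form is singular at B0′ = 1).  The solver's result is polished with
  damped Gauss–Newton iterations to the exact stationary point
  (Jᵀr = 0): second temperature differences of G amplify any solver
  termination noise into C_p, so fits of near-identical isotherms must
  agree at the ~1e-13 level, far beyond the optimizer's stopping
  tolerance.
* **Isotherm minimization.**  Each `F(V)` isotherm is refit with the
  Murnaghan form and minimized analytically (`V(p)` closed form); this
  gives a smooth `V_eq(T)` and hence stable `α_p`.  An isotherm whose
  minimum escapes the volume grid is fit anyway and flagged with a
  warning (extrapolated).
* **Derivatives.**  `S` and `C_v` use the analytic oscillator formulas
  at `(T, V_eq(T))`; `H = G + T·S`; `C_p = dH/dT` and
  `α_p = (1/V)·dV/dT` by central differences with step 1 K, shrunk to
  `max(T/40, 0.01)` K below 40 K where `C_p(T)` is strongly curved
  (otherwise truncation error can push `C_p` below `C_v`).
  `κ_T = 1/B(V_eq)` with `B(V) = B0·(V0/V)^B0′` from the refitted
  isotherm.
* **Off-node frequencies.**  Models using raw (non-extrapolated)
  phonons need frequencies between and beyond the sampled volumes when
  thermal expansion moves `V_eq` off the nodes.  Per rank, `ln ν` is
  interpolated linearly in `ln V` and continued with the edge slopes —
  exact at the nodes, exact everywhere for power-law data, and a
  locally-power-law (constant-γ) continuation outside the window.
* **Mode filtering.**  At the Γ point, up to three of the lowest-rank
  modes with |ν| < 0.3 THz at every volume are dropped (acoustic modes
  are zero up to numerical noise and their γ is undefined); the
  threshold guard means small deliberate mode sets (e.g. one-mode
  Einstein crystals) are not emptied.  Imaginary modes (stored as
  negative frequencies) below 0.1 THz in magnitude are dropped with a
  warning; larger ones abort — a genuinely unstable structure has no
  quasi-harmonic free energy.  Q-points are labeled with fractional
  coordinates in the phonon files; when absent the first block is taken
  as Γ.
* **Grids.**  Default temperature grid 0–400 K in 5 K steps (covers
  ambient comparisons and typical fusion temperatures); default
  pressure 0 GPa.  The default volume grid for a composite surface is
  the underlying phonon scan's volumes, translated by ΔV0 for shifted
  models so the new minimum stays bracketed (the off-window A_vib there
  comes from the extrapolation rules above).
* **Crossing detection.**  Polymorph ΔG(T) roots are located by linear
  interpolation between grid points; |ΔG| < 0.01 kJ/mol throughout the
  assessed range is classified "indeterminate" (inside sub-kJ
  experimental uncertainty).  The classification window defaults to
  the table range, or [0, T_fus] when a fusion temperature is given.

## Sensitivity probes

`sensitivity_entropy_offset` adds a constant δS (a residual-entropy
hypothesis): S → S + δS, G → G − T·δS, H unchanged — against an
unmodified partner the ΔG slope tilts by exactly −δS.
`sensitivity_cp_scale` multiplies C_p by a constant factor f and
re-integrates: since S(T) = S(0) + ∫C_p/T′ dT′ and
H(T) = H(0) + ∫C_p dT′, the result is expressed exactly through the
table's own 0 K anchors (S → S0 + f·(S − S0), H → H0 + f·(H − H0),
G = H − T·S), which makes f = 1 the identity and scaling involutive to
machine precision; the table must start at 0 K.

## Fragment lattice energies

All molecular pairs whose closest atom–atom contact lies within a
cutoff (8 Å default; closest-contact rather than centroid distance, as
it is robust for elongated molecules) are enumerated over periodic
images and deduplicated into symmetry-unique records by a sorted
inter-dimer atomic-distance fingerprint (tolerance 1e-4 Å), which
collapses symmetry-equivalent pairs whether or not symmetry operations
are supplied.  A record's multiplicity counts the anchored (ordered)
pairs it represents, so the per-cell lattice energy

    E_lat = Σ_i (E_i − E_i^gas) + ½ · Σ_unique m_ij · ε_ij

carries the ½ that prevents double counting; the convention is
validated against brute-force periodic pair sums.  Monomer and dimer
energies are external inputs (CSV); a Lennard-Jones provider exists for
testing only.  Molecule perception uses Cordero covalent radii with a
0.4 Å bond margin, periodic images included; single-atom molecules are
allowed and logged.

## The synthetic model crystals

The generator emulates a two-level ingredient pair with fully analytic
physics: energies exactly Murnaghan per level, frequencies exactly
ν⁰·(V/V0)^(−γ) per mode, optional seeded multiplicative noise.
Defaults describe a small-molecule pharmaceutical crystal: Z = 4,
48 optical modes log-spaced 0.5–95 THz (lattice modes through C–H
stretches), γ decaying from ~3 to ~0 with frequency, V0 = 920 Å³
(≈230 Å³ per molecule), B0 = 10 GPa, B0′ = 5; the cheap level's minimum
at 91% of the costly one's (the 8–10% overbinding band) with a 50%
stiffer curvature (B0 = 15 GPa).  One Γ-only q-point by default, with a
two-q-point option exercising weights; three exact-zero acoustic modes
are emitted at Γ so the filtering path is exercised.

What the generator does **not** emulate: eigenvector mixing between
modes (rank matching is exact by construction), anharmonicity, disorder
or defect entropy, and systematic error patterns of real method pairs
beyond the configurable minima offset and curvature ratio.  Passing
tests therefore demonstrate the correctness of the *processing* — fits,
transforms, thermodynamics, sums — not the physical accuracy of any
particular method combination on real crystals.

The end-to-end recovery check runs the full M4 pipeline from written
ingredient files and compares against an independent oracle that
minimizes the exact analytic F(T, V) directly.  It is performed in the
regime the Shift/Extra construction assumes: equal per-mode γ at both
levels, and a cheap curve whose shape about the minimum transfers —
equal E″(V0), i.e. B0_low/V0_low = B0_high/V0_high, and equal E0.  Only
the minimum volume differs (by the default 9%).  Outside that regime
the composite result differs from the costly reference by construction
— that residual is the method's approximation error, not a pipeline
defect.

## Problem sizes

Test and acceptance runs use 7-volume scans, 48–100 modes, 0–400 K
grids at 5–10 K steps, and toy lattices with ≤ 2 molecules per cell —
sizes at which every oracle (brute-force lattice sums, dense scans,
closed forms) is exact and fast while exercising the same code paths as
production-size inputs.

## Known limitations

* Harmonic/quasi-harmonic only: no explicit anharmonicity, no
  sublimation equilibria, no thermal conductivity.
* Sorted-rank mode matching can mispair modes through avoided
  crossings; fitting over several volumes averages much of this out,
  and neighboring-rank γ similarity is monitored as a regression check
  rather than asserted.
* Murnaghan only (the form the workflow standardizes on); other EOS
  families are out of scope.
* The fingerprint-based dimer deduplication can in principle merge
  geometrically distinct pairs with identical distance multisets;
  at the 1e-4 Å tolerance this does not occur for realistic inputs.
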