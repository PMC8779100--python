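# Methods

This note records the models, conventions and numerical choices behind
`polyconf`, and what the synthetic generators do and do not emulate.

## Angle domain and trajectory conventions

All dihedral angles live in degrees on the canonical domain (−180, 180];
every comparison happens after wrapping (`wrap_degrees`, idempotent).
Φ(i) is the torsion C(i−1)–N(i)–CA(i)–C(i) and Ψ(i) is
N(i)–CA(i)–C(i)–N(i+1), with the IUPAC sign convention (clockwise rotation
of the far bond viewed along the near bond is negative); cis = 0°, trans
canonicalized to +180°.  Terminal residues lack one neighbour, so Φ of
residue 1 and Ψ of residue n are undefined (NaN markers), and both terminal
residues are excluded from all statistics — a 32-residue chain contributes
30 analyzed monomers.

Coordinates are stored in nm and times in ns internally (PDB Å and ps are
converted on read through MDAnalysis).  Equilibration discard removes the
first ⌈fraction·n_frames⌉ frames (default fraction 0.1, matching the common
practice of discarding the first tenth of a production run); an absolute
time may be given instead.  Dihedral tables are UTF-8 delimited text with a
required header (`time_ns,residue,phi_deg,psi_deg`), comma or tab
auto-detected; rows may appear in any order but the frame × residue grid
must be complete.

## Region sets

A region set is an explicit partition of the Ramachandran torus into named
states; everything unassigned is `other`.  `standard_literature` encodes
the literature box bounds for deprotonated Asp/Glu residues:

| state | Φ | Ψ |
|---|---|---|
| αR | [−90, −30] | [−90, 0] |
| αL | [30, 90] | [0, 90] |
| PPII | [−104, −46] | [116, 174] |
| β | [−180, −104) | [104, 180] |

Boxes are half-open (lower inclusive) only where needed to keep neighbours
disjoint; bounds printed as closed in the literature stay closed.  The β
region's Ψ clause is sometimes printed with inverted order ("180 ≤ Ψ ≤
104"); it is read here as the interval [104, 180].  Partition validity — no
two labeled regions claim the same point — is asserted on a 1° grid over
the full torus (129,600 points) for every shipped and user-supplied set.

The integration variants (`charmm_integration`, `amber99_integration`,
`opls_integration`) reproduce the area topology used when populations are
read off force-field-specific density maps: area 0 is the canonical αR box;
area 1 is the remaining screw population, represented as the complement of
the αR box within an enclosing screw box Φ ∈ [−160, −30], Ψ ∈ [−90, 50]
(decomposed into two disjoint rectangles).  In CHARMM-style maps the αR and
3.10 basins separate, so area 1 is labeled `3.10`; in AMBER/OPLS-style maps
they merge and area 1 is the `additional_screw` population.  These bounds
are reconstructions of figure areas, not printed values, and carry an
`approximate` flag; all bounds are overridable through the YAML
serialization.  The sparsely populated ζ (−135°, 60°) and γ′ (−80°, 80°)
basins ship as optional 30°-half-width boxes in
`standard_literature_extended`, trimmed at Φ = −110° (between them) and at
Ψ = 104° (γ′ against β) so the partition invariant survives; they are off
by default.

Fractions can be computed two ways: direct per-sample classification with
block-SD errors, or integration of a normalized 2-D histogram with bins
assigned by bin-center membership.  When every box bound lies on a bin edge
the two agree exactly (all standard bounds are even degrees, so 2° bins
align); otherwise they differ by at most one bin-row of mass.

## Sequence statistics

Within a frame, a maximal run of contiguous monomers in one state is an
equiconformational sequence; runs are non-wrapping (the chain is linear)
and truncated runs at chain ends count at their actual length.  The
monomer fraction in sequences of length ≥ m is
F = (1/t) Σ_j Σ_{i≥m} i·R_ij / n with t frames and n analyzed monomers;
the default threshold m = 4 corresponds to at least one helical turn (3.6
residues per turn).  Maximal-run decomposition partitions the target
monomers, so Σ_i i·R_ij equals the per-frame state count (a test invariant),
F is non-increasing in m, and F at m = 1 equals the plain state fraction.
Runs are frame-wise only; no temporal persistence is required.  The same
machinery serves β sequences (target β, m = 4) and, applied to the
transposed label matrix, temporal lifetimes.

## Geometry and counterion bridges

R_g is the mass-weighted RMS distance from the center of mass; end-to-end
distance is CA(1)–CA(n) without minimum image (the chain is whole).  An ion
bridges residues a and b when it lies within a species-specific cutoff of
at least one side-chain carboxylate oxygen of each, with |a − b| ≥ 3
("distant" groups, excluding nearest-neighbour contacts).  Cutoff defaults
(Na⁺–O 0.32 nm, K⁺–O 0.36 nm) are typical first minima of ion–carboxylate
oxygen radial distribution functions; both the cutoffs and the separation
rule are configurable, and results that depend on them should be reported
with the parameter values attached.  Minimum-image distances are used only
when an orthorhombic box is present; triclinic boxes are rejected.  The
per-frame bridge fraction is (distinct residues appearing in ≥ 1 bridge) /
(carboxylate-bearing residues), averaged over time with a block SD.

## Autocorrelation and KWW fitting

The distance ACF is the mean-subtracted, variance-normalized estimator
C(t) = ⟨δd(t₀)δd(t₀+t)⟩/⟨δd²⟩ averaged over all origins, per-lag
normalization 1/(N−t); the dihedral ACF embeds each angle as a unit vector
u = (cos θ, sin θ), averages u(t₀)·u(t₀+t) over origins, then over residues
(equally weighted; columns with undefined termini are skipped), and
rescales so C(0) = 1 — making it invariant to ±360° jumps.  Both use an
FFT fast path that matches the O(N²) lag-sum definition to 10⁻¹⁰ in tests,
and report lags up to half the series length.

Fits minimize least squares of A·exp(−(t/τ)^β) with bounds τ > 0,
β ∈ (0.05, 2], A ∈ (0.05, 1.5], with two starts (β₀ = 1.0 and 0.5, τ₀ at
the window midpoint); the lower-cost solution wins, and non-convergence of
both raises with diagnostics.  The default window runs from the first
nonzero lag (relaxation faster than the sampling step is unresolvable) to
the first crossing of the noise floor C = 0.02, and needs ≥ 8 points.  An
explicitly passed window is honored as given, including lag 0; that option
exists for recovery experiments on synthetic series whose C(0) = 1 is exact
by construction — when the true relaxation time is near the lag spacing the
default window leaves a 3-parameter fit with ~3 informative points, while
anchoring the exact origin restores identifiability.  (Conversely, when a
synthetic series has amplitude < 1 the forced C(0) = 1 point contradicts
the model and must stay out of the window.)  Both the fit parameter τ and
the integral mean τ_mean = (τ/β)Γ(1/β) are reported; comparisons use τ
unless stated otherwise.  Dihedral ACFs are averaged over residues before a
single fit; per-residue fitting is available as an option.

## Synthetic generators

The generators reproduce the statistical structure the analyses assume, at
the default study conditions: 32 residues, 0.1 ns frame spacing, and
stationary fractions/lifetimes of order the examples use (helix-forming
states ~20–30% with ~1 ns lifetimes, stretched states ~40–50% with ~2 ns).
Each residue evolves as an independent discrete-time Markov chain with stay
probability q_s = exp(−dt/λ_s) and off-diagonal transitions proportional to
the target fractions π_{s'}; this proportional-attraction construction only
approximates π, so the exact stationary law of the constructed matrix
(solved as its unit left eigenvector) is reported alongside and used by all
recovery tests.  Emissions draw (Φ, Ψ) from a truncated Gaussian about the
centroid of the state's widest box (default SD 10°), guaranteeing
classification closure; chains initialize from the exact law and are
seed-reproducible.  Bead chains bend by a state-dependent angle about a
random perpendicular axis per step (stretched states nearly straight, screw
states sharply turned), providing R_g/end-to-end test beds.  Bridge
fixtures move one carboxylate oxygen of each programmed pair to a meeting
point 0.20 nm from a shared ion, park all other ions ≥ 0.6 nm from every
oxygen, and allow per-frame toggling; a residue joins at most one pair.

What the generators do **not** emulate: excluded volume, electrostatics,
solvent, correlations between residues (an optional pairing of β-blocks
exists for timeline illustrations but is off by default), and any coupling
between dihedral state and the 3-D geometry beyond the per-state bend
angle.  Passing tests therefore demonstrate correctness of the estimators
and statistics under known laws, not force-field realism.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make
sampling error negligible relative to the assertions: 10⁵ frames × 30
residues for Markov recovery, 10⁵ emissions per state for classification
closure, 500-frame × 30-monomer matrices (×100) for brute-force
equivalence, 50 seeds per grid point for KWW recovery, and N ≤ 2000 series
for the O(N²) ACF oracles.

## Known limitations

- Bridge criteria are contact-distance only; no residence-time kinetics,
  RDFs, or condensation analysis.
- No DSSP-style hydrogen-bond secondary structure; state identity is purely
  dihedral-region membership.
- No error bars on fitted KWW parameters beyond the residual RMS.
- Region bounds for the integration variants are documented approximations
  of figure areas; quantitative comparisons should prefer
  `standard_literature` or user-supplied bounds.
- Trajectory reading supports whatever MDAnalysis reads (PDB/GRO topology,
  XTC/DCD trajectories); trajectory *writing* is limited to multi-model PDB
  fixtures.
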