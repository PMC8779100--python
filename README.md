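# polyconf

Conformational and relaxation analysis of polypeptide molecular-dynamics
trajectories, aimed at anionic homo-polypeptides such as fully deprotonated
poly(glutamic acid) (PGA) and poly(aspartic acid) (PASA) with monovalent
counterions.  `polyconf` takes per-residue backbone dihedral time series (or
standard topology + trajectory files) and measures the observables that
characterize local structure and dynamics of such chains:

- **Ramachandran conformer classification.**  Validated region sets
  partition the (Φ, Ψ) torus into the conformational basins of the field
  (αR, αL, PPII, β-sheet, 3.10 / "additional screw", optional ζ and γ′);
  every residue-frame is labeled, and per-state population fractions carry
  block-averaged standard deviations.  Fractions may equivalently be
  obtained by integrating a normalized 2-D dihedral density over regions.
- **Equiconformational sequences.**  For a target state *s*, maximal runs of
  contiguous monomers in *s* are counted per frame (R<sub>ij</sub> runs of
  exact length *i* in frame *j*), and the fraction of monomers in runs of at
  least one helical turn (> 3 monomers) is

  F<sub>s</sub> = (1/t) Σ<sub>j</sub> Σ<sub>i≥4</sub> i·R<sub>ij</sub> / n,

  with *t* analyzed frames and *n* = 30 analyzed monomers for a 32-residue
  chain (termini excluded).
- **Chain geometry and counterion bridges.**  Radius of gyration,
  CA(1)–CA(n) end-to-end distance, and detection of ion bridges: a
  counterion within a species-specific cutoff (Na⁺–O 0.32 nm, K⁺–O 0.36 nm)
  of carboxylate oxygens of two residues separated by ≥ 3 positions.
- **Relaxation dynamics.**  Autocorrelation functions of the end-to-end
  distance (mean-subtracted, variance-normalized) and of dihedral angles
  (unit-vector embedding, circular-safe), fitted with the stretched
  exponential f(t) = A·exp(−(t/τ)<sup>β</sup>) (KWW); the mean relaxation
  time follows as τ<sub>mean</sub> = (τ/β)·Γ(1/β).
- **Synthetic trajectory generator.**  Residue-wise Markov switching among
  conformational states with prescribed stationary fractions and lifetimes,
  dihedral emission truncated to region boxes, bead chains with
  state-dependent bending, ion placements realizing programmed bridge sets,
  and noisy KWW series — every analysis stage is testable against known
  ground truth without running MD.
- A packaged table of published spectroscopic conformer populations for
  Asp/Glu peptides and PGA, with directional-bound handling, for comparing
  simulated ensembles against experiment.

## Worked example

```python
import polyconf as pc

spec = pc.GeneratorSpec(
    states={"alphaR": (0.25, 1.2), "PPII": (0.45, 2.0), "beta": (0.30, 1.5)},
    n_frames=5000, n_residues=32, dt=0.1, seed=42)
regions = pc.builtin_region_set("standard_literature")
traj = pc.emit_dihedrals(pc.markov_state_trajectory(spec), regions, spec)
traj = pc.discard_equilibration(traj, fraction=0.1)

states = pc.classify_trajectory(traj, regions)      # 30 analyzed monomers
table = pc.state_fractions(states, n_blocks=5)
print(table.fractions["alphaR"], table.errors["alphaR"])

record = pc.run_lengths(states, "alphaR")
print(pc.sequence_fraction(record, min_len=4))
```

Running `examples/classify_fractions.py` prints

```
4500 frames x 30 monomers
alphaR   fraction 0.2267 +/- 0.0143   (exact law 0.2197)
PPII     fraction 0.4760 +/- 0.0099   (exact law 0.4753)
beta     fraction 0.2973 +/- 0.0070   (exact law 0.3050)
```

i.e., the classified populations recover the exact stationary law of the
generator's transition matrix within the block standard deviations.  The
other scripts in `examples/` walk through sequence statistics, KWW fitting,
bridge detection, conformation timelines and the experimental comparison,
each printing the numbers it computes and what they mean.

A thin CLI mirrors the library (`polyconf simulate | classify | fractions |
sequences | geometry | dynamics | report`), e.g.

```sh
polyconf --out-dir run --seed 4 simulate --n-frames 2000
polyconf --out-dir run report run/synthetic_dihedrals.csv
```

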