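"""Fraction of monomers in helical sequences of at least one turn.

An alpha-helix has 3.6 residues per turn, so only runs longer than three
monomers can be part of a real helix.  The sequence fraction converts
per-frame maximal-run counts into the fraction of the 30 analyzed monomers
sitting in such runs.
"""

import polyconf as pc

spec = pc.GeneratorSpec(
    states={"alphaR": (0.35, 2.5), "PPII": (0.40, 1.5), "beta": (0.25, 1.5)},
    n_frames=5000, n_residues=32, dt=0.1, seed=11)
regions = pc.builtin_region_set("standard_literature")
traj = pc.emit_dihedrals(pc.markov_state_trajectory(spec), regions, spec)
states = pc.classify_trajectory(traj, regions)

record = pc.run_lengths(states, "alphaR")
plain = pc.sequence_fraction(record, min_len=1)
helical = pc.sequence_fraction(record, min_len=4)
hist = pc.length_histogram(record)

print(f"alphaR state fraction:                 {plain:.4f}")
print(f"alphaR monomers in runs >= 4 (F_alpha): {helical:.4f}")
print("mean runs per frame by length:")
for i in range(1, 9):
    print(f"  length {i}: {hist[i]:.3f}")
print("F_alpha <= the plain fraction: only monomers inside runs of at")
print("least one helical turn count toward helical sequences.")
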