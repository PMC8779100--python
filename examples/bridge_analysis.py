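"""Counterion bridges between sequence-distant carboxyl groups.

Builds a coordinate fixture with one programmed Na+ bridge between residues
3 and 10 of a 32-residue chain, detects bridges with the contact-distance
criterion (Na+-O cutoff 0.32 nm, residue separation >= 3) and reports the
fraction of carboxyl groups engaged in bridges.
"""

import polyconf as pc

fixture = pc.bridge_fixture(32, bridged_pairs=[(3, 10)], n_frames=10)
bridges = pc.detect_bridges(fixture, frame=0)
report = pc.bridge_fraction(fixture, n_blocks=5)

print("bridges in frame 0:")
for b in sorted(bridges, key=lambda b: b.residue_a):
    print(f"  ion atom {b.ion_index} links residues {b.residue_a} and {b.residue_b}")
print(f"bridged carboxyl fraction: {report.fraction:.4f} +/- {report.error:.4f}")
print("2 of the 32 carboxyl groups take part in the single bridge, giving")
print("2/32 = 0.0625; such bridges compact the chain and slow its relaxation.")
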