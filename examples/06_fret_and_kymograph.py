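"""Donor quenching as a folding reporter: FRET model and kymograph.

The donor and acceptor dyes sit at the domain termini: ~20 A apart when
folded (donor quenched by energy transfer, Forster radius 65 A) and beyond
100 A when the chain is pulled open (donor bright).  The kymograph
generator renders this as a scanned-line fluorescence image with bead
autofluorescence bands and Poisson counting noise.
"""

import numpy as np

from tunnelfold import fret_efficiency, simulate_kymograph

print("FRET efficiency, R0 = 65 A:")
for r in (20.0, 65.0, 100.0, 150.0):
    e = fret_efficiency(r, 65.0)
    print(f"  r = {r:5.1f} A: E = {e:.4f}  (donor {'dark' if e > 0.5 else 'bright'})")

# a molecule that unfolds halfway through the scan series
distances = np.concatenate([np.full(40, 20.0), np.full(40, 130.0)])
counts, (top, mid, bottom) = simulate_kymograph(distances, seed=0)
inter = counts[mid, :].mean(axis=0)
print(f"\nkymograph: {counts.shape[0]} pixels x {counts.shape[1]} scans")
print(f"inter-bead donor signal, folded half:   {inter[:40].mean():6.1f} counts")
print(f"inter-bead donor signal, unfolded half: {inter[40:].mean():6.1f} counts")
print(f"bead autofluorescence bands:            {counts[top, :].mean():6.1f} counts")
print("\nThe donor lights up only in the unfolded half: exactly the")
print("appears-under-tension signature used to corroborate mechanical")
print("unfolding events in the force channel.")
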