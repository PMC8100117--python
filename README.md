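# tunnelfold

Coarse-grained simulation and single-molecule analysis of protein folding
inside the ribosomal exit tunnel.

Small protein domains can fold before leaving the ribosome, inside the exit
tunnel's vestibule — a crowded, negatively charged channel through the large
subunit.  Optical-tweezers experiments probe this by pulling on a nascent
chain tethered between DNA handles and watching for sudden contour-length
changes; simulations ask *why* folding there is not merely possible but
easier than outside.  `tunnelfold` implements both sides of that study as a
reusable Python library:

* **Coarse-grained model** — one bead per residue at the Cα position, a
  structure-based (Gō-type) contact energy, short-range ribosome repulsion,
  and screened electrostatics
  `V = Σ q_i q_j e^(−r/λ_D) / (4π ε_d(r) ε_0 r)` with the distance-dependent
  dielectric `ε_d(r) = (5.2+ε_s)/2 + (ε_s−5.2)/2 · tanh[(r−r_m)/σ_ε]`
  (ε_s = 80, r_m = 8 Å, σ_ε = 10 Å); charges −1 for Asp/Glu and nucleotide
  phosphates, +1 for Arg/Lys, +0.5 for His.
* **Langevin kinetics** — overdamped constant-force dynamics (numba), with
  folding/unfolding rates from mean first passage times between states
  defined on the fraction of native contacts Q.
* **Free-energy profiles** — umbrella sampling along Q recombined by WHAM,
  folding stability ΔG from basin populations, and the decomposition
  ΔG = ΔE − TΔS across temperatures.
* **Force-spectroscopy theory** — the Dudko–Hummer–Szabo rate law
  `k(F) = k0 (1 − νFx‡/ΔG‡)^{1/ν−1} exp{ΔG‡[1 − (1 − νFx‡/ΔG‡)^{1/ν}]}`
  (ν = 2/3), its fits, and ramp rupture-force densities
  `p(F) = k(F)/Ḟ · exp(−∫₀^F k/Ḟ dF′)`.
* **Trace analysis** — extensible-WLC (DNA handles) + Odijk-WLC (protein)
  series tether model, rip detection in pull-relax cycles, contour-length
  changes in nm and residues (0.365 nm/aa), force statistics with
  Mann–Whitney tests, refolding frequencies, and the FRET quench model
  `E = 1/(1 + (r/R0)⁶)`.
* **Synthetic data** — a deterministic 29-residue zinc-finger surrogate, a
  charged cylindrical tunnel surrogate, pull-relax traces with planted
  ground truth, and donor-quench kymographs; every generator is seeded.

The library API is the interface; `examples/` holds one short narrative
script per capability, and a thin `tunnelfold` CLI wraps the common
pipelines (`simulate`, `rates`, `fes`, `decompose`, `pfdist`,
`analyze-traces`, `synth`).

## Worked example

`python examples/05_trace_analysis.py` generates 40 synthetic pull-relax
cycles with a planted 31-residue contour-length change, runs the detection
and fitting pipeline, and prints:

```
40 cycles: 23 unfolding and 34 refolding rips refined (40 planted unfolds)
  unfold: 23.9 +/- 0.7 pN (n = 23)
  refold: 19.7 +/- 0.8 pN (n = 34)
  Mann-Whitney U two-sided p = 5.99e-04
contour-length change on unfolding: 31.7 +/- 0.5 aa (planted: 31.0 aa)
refolding frequency: 88% of cycles (95% CI 73-96%)
```

The unfolding rips release 31.7 ± 0.5 residues of contour — recovering the
planted 31-aa domain release — at higher force than the refolding rips
(the Mann–Whitney p-value tests that separation), and most relax phases
show a refold, as expected for the zinc-bound domain.  Ruptures above the
35 pN handle-model limit are detected but flagged unusable for contour
fitting, which is why fewer unfolds are refined than planted.

A minimal library session:

```python
import numpy as np
from tunnelfold import (EnergyParams, PullProtocol, build_topology,
                        make_toy_zincfinger, make_tunnel)
from tunnelfold.dynamics import rate_vs_force

toy, tunnel = make_toy_zincfinger(), make_tunnel()
params = EnergyParams()                     # electrostatics on by default
chain = build_topology(toy.positions, toy.sequence, 26, tunnel,
                       coordination=toy.coordination, params=params)
table = rate_vs_force(chain, tunnel, params, forces=[0.5], n_replicas=20,
                      direction="folding", seed=7, method="mle",
                      protocol=PullProtocol(max_steps=300_000, dt=5e-5))
print(table)   # folding rate of the domain deep in the vestibule
```

Repeating this at linker length 34 (domain at the tunnel mouth) gives a
smaller folding rate: with the charged wall lining switched on, the deeper
construct folds no slower — the electrostatic signature the simulations
exist to probe.

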