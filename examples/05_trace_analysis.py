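"""Analyse synthetic optical-tweezers pull-relax traces end to end.

Generates pull-relax cycles with planted two-state transitions (ground
truth known), detects unfolding/refolding rips, refines each rip's
contour-length change by worm-like-chain segment fits, and prints the
summary statistics an experimentalist would report.
"""

import numpy as np

from tunnelfold import (
    SyntheticTraceConfig,
    TetherModel,
    contour_length_change,
    detect_transitions,
    force_stats,
    refolding_frequency,
    simulate_trace,
)

config = SyntheticTraceConfig(n_cycles=40, seed=8)
trace, truth = simulate_trace(config)
model = TetherModel(delta_Lc=config.delta_Lc)

events = detect_transitions(trace, model)
refined = []
for event in events:
    try:
        refined.append(contour_length_change(event, trace, model))
    except ValueError:
        pass  # rupture too close to the ramp top to fit the released state

unfolds = [e for e in refined if e.direction == "unfold"]
refolds = [e for e in refined if e.direction == "refold"]
print(f"{config.n_cycles} cycles: {len(unfolds)} unfolding and "
      f"{len(refolds)} refolding rips refined "
      f"({sum(1 for t in truth if t['kind'] == 'unfold')} planted unfolds)")

groups = {
    "unfold": np.array([e.force for e in unfolds]),
    "refold": np.array([e.force for e in refolds]),
}
stats, pvals = force_stats(groups)
for s in stats:
    print(f"  {s.label}: {s.mean:.1f} +/- {s.sem:.1f} pN (n = {s.n})")
print(f"  Mann-Whitney U two-sided p = {pvals['p'].iloc[0]:.2e}")

dlc = np.array([e.delta_Lc_aa for e in unfolds])
print(f"\ncontour-length change on unfolding: {dlc.mean():.1f} +/- "
      f"{dlc.std(ddof=1)/np.sqrt(len(dlc)):.1f} aa (planted: 31.0 aa)")

frac, (lo, hi) = refolding_frequency(config.n_cycles, events)
print(f"refolding frequency: {100*frac:.0f}% of cycles "
      f"(95% CI {100*lo:.0f}-{100*hi:.0f}%)")
print("\nWith zinc=False the generator drops the per-cycle refolding")
print("probability to ~17%, emulating the rarely-refolding ion-free domain.")
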