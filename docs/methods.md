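# Methods

`tunnelfold` models the folding of a small zinc-finger protein domain while
it is still tethered inside the ribosomal exit tunnel, and the
single-molecule force-spectroscopy experiments used to observe it.  This
note records the models, the defaults and why they were chosen, what the
synthetic data do and do not emulate, and the numerical choices that matter.

## Coarse-grained model

Each protein residue is one bead at the Cα position; nucleic-acid residues
in user-supplied environments are three beads (P, C4', N3).  The energy
function is structure-based (Gō-type): attractive terms exist only between
residue pairs in contact in the native structure.

* **Native contacts.** Pairs with sequence separation ≥ 3 and Cα–Cα
  distance < 0.8 nm in the native structure.  Each contact is a 12-10 well
  `eps [5 (r0/r)^12 − 6 (r0/r)^10]` with its minimum −eps at the native
  distance r0.  Default `eps = 1.5 kBT`: this places the packaged toy
  domain slightly above its folding midpoint at the reference temperature,
  so that both folding and unfolding events occur spontaneously within
  desk-scale trajectories (10^5–10^6 steps).  A deeply stable fold (eps ≳
  2.5) never unfolds on these timescales at any realistic force — the
  narrow 12-10 wells make the mechanical transition state extremely close
  to the native minimum — so the marginal regime is the one in which
  force-dependent kinetics are measurable at this problem size.
* **Bonds.** Harmonic, rest length 0.38 nm, stiffness 1000 kBT/nm²; no
  angle or dihedral terms.
* **Excluded volume.** `eps_rep (sigma/r)^12` between non-native,
  non-bonded chain pairs and all chain–environment pairs; chain bead radius
  0.19 nm (pair sigma 0.38 nm, just below the tightest native distances of
  the toy fold), environment bead radius 0.25 nm.  The repulsion is capped
  below 0.4 sigma so overlapping configurations give large finite energies
  rather than overflow.
* **Electrostatics.** Screened Coulomb
  `V = q_i q_j exp(−r/λ_D) / (4π ε_d(r) ε_0 r)` over every charged pair
  (chain–chain and chain–environment), with the distance-dependent
  dielectric `ε_d(r) = (5.2+80)/2 + (80−5.2)/2 · tanh[(r − 0.8 nm)/1.0 nm]`
  — 5.2 is the limiting permittivity next to a charged residue, 80 bulk
  water at 298 K.  Charges: D/E −1, R/K +1, H +0.5, nucleotide phosphate
  beads −1, all else 0.  The Debye length defaults to 1.0 nm (≈100 mM
  monovalent salt); interactions are cut off at 3 λ_D, where the screened
  pair energy is below ~0.01 kBT.
* **Optional non-specific attraction.** A `−2 sqrt(a·eps_rep) (sigma/r)^6`
  term between chain and environment beads, giving a well of depth exactly
  `a` when combined with the repulsion; default off.
* **Zinc.** The ion is not a bead.  With zinc "present" the six pairwise
  contacts among the two-His/two-Cys coordination quadruple get doubled
  well depth; "absent" removes them, weakening the native basin — the
  mechanism behind the domain's rare refolding without the ion is left
  open, this is the minimal representation that reproduces a weaker basin.
* **Units.** Lengths nm, energies kBT at the 298 K reference, forces pN,
  with kBT = 4.114 pN·nm; all conversions go through `tunnelfold.units`.

## Geometry: tunnel surrogate and tethering

The packaged environment is a cylinder of length 8 nm and radius 1.0 nm
that widens linearly to 1.8 nm over its last 2 nm (the vestibule), walls
tiled with beads at 0.47 nm spacing, plus a flat base around the tether
point and one external anchor bead standing in for the N-terminus of
ribosomal protein uL4 (the anchor is a pulling reference only and carries
no excluded volume).  A seeded random 30% of wall beads carry −1,
representing the rRNA phosphate lining.  Real coordinates can be loaded
instead; nothing in the algorithms assumes the surrogate.

The chain C-terminus is fixed at the tunnel base (the peptidyl-transferase
centre surrogate); the linker (Gly/Ser repeat) zig-zags up the axis at an
axial rise of 0.26 nm per residue, placing the folded domain inside the
vestibule at linker length L = 26, at the mouth at L = 34, and clear of
the exit at L = 40 — the three constructs the study conditions compare.
Constant force acts on the chain N-terminus along the instantaneous
anchor-to-bead direction (or a fixed axis in free-chain tests).

## Dynamics and rates

First-order overdamped (Euler–Maruyama) Langevin integration with unit
friction per bead, so the diffusion constant equals the reduced
temperature and time is in units of friction·nm²/kBT; the mapping to
seconds is left symbolic.  The default timestep 5×10⁻⁵ is set by the
stiffest native-contact wells of the toy system (the integrator refuses
timesteps beyond the bond-stability bound and aborts on per-step
displacements above 1 nm).  Environment interactions use Verlet neighbour
lists rebuilt every 20 steps with a 0.5 nm skin.

States are defined on the fraction of native contacts: folded Q ≥ 0.8,
unfolded Q ≤ 0.2 (widely separated to suppress recrossing).  Rates come
from mean first passage times over replica simulations: by default
k = 1/⟨t⟩ over uncensored passages, with a censoring-aware exponential
maximum-likelihood option (k = events / total simulated time) that the
force-scan utilities use, since high-force folding runs are legitimately
censored.  Bootstrap confidence intervals are seeded and reported.

Unfolding replicas start from the native structure (10³ equilibration
steps at the target force).  Folding replicas start from a straight chain
relaxed at the target force; because the taut chain must first recoil — a
Rouse-relaxation process that takes ~10⁵ steps for these chain lengths —
the relaxation is 1.5×10⁵ steps per replica, and a replica that crosses
the folded threshold during relaxation counts as an immediate event.  The
benchmark protocols (20 replicas × 4 forces; force grids spanning 5–95 pN
for unfolding and 0.5–9 pN for folding on the free domain, a common 0.5 pN
for the in-tunnel comparison) are the problem sizes at which transitions
occur within a few × 10⁵ steps per replica; the unfolding grid extends to
high force because the marginal toy's mechanical transition state lies
very close to its native minimum, so rate changes only become resolvable
against replica noise over a wide force span.

## Umbrella sampling and WHAM

The bias coordinate is a smoothed Q (logistic switch of width 0.05 nm per
contact) so the harmonic window bias `½ k_w (Q − Q0)²` has a well-defined
force; the hard-count Q is retained for state detection.  Windows run in
descending-centre order, each seeded from the previous window's final
configuration (steering the chain gradually from folded to unfolded), with
a 20% burn-in discarded and a neighbour-overlap audit afterwards.  WHAM is
the standard binned self-consistent iteration (50 bins on [0,1], relative
tolerance 10⁻⁷, order-invariant, empty bins flagged as NaN rather than
interpolated).  Folding stability is the log population ratio of the
Q > 0.7 and Q < 0.3 basins; fitting stabilities across reduced
temperatures {0.9, 1.0, 1.1} to ΔG = ΔE − TΔS separates energetic from
configurational-entropy contributions (in a solvent-free model all solvent
effects are inside ΔE).

A known limitation: resolving the *difference* in fitted ΔS between the
on-tunnel and free systems (the confinement entropy effect) is beyond
desk-scale sampling — the unfolded chain's in/out-of-tunnel relaxation is
Rouse-slow, and at 9 windows × 25k steps × 3 temperatures the fitted ΔS
carries seed-to-seed noise of tens of kB.  The decomposition machinery is
therefore validated against analytic oracles, and the confinement effect
itself is asserted through a direct geometric observable (wall exclusion
of the unfolded ensemble) rather than through ΔΔS.

## Force-spectroscopy kinetics

The single-barrier rate law
`k(F) = k0 (1 − ν F x‡/ΔG‡)^{1/ν−1} exp{ΔG‡[1 − (1 − ν F x‡/ΔG‡)^{1/ν}]}`
with ν = 2/3 (linear-cubic landscape; ν = 1 recovers the Bell law) is
evaluated with F x‡ expressed in kBT; the refolding direction maps
F → −F.  Beyond the barrier-vanishing force the law is undefined and the
evaluator raises rather than clamping.  Fits are weighted least squares on
log k with ν fixed at 2/3 (a free-ν mode exists for sensitivity checks);
inside the optimiser the barrier term is clamped so trial parameters
outside the valid region are penalised smoothly instead of raising.

Under a force ramp Ḟ the rupture-force density is
`p(F) = k(F)/Ḟ · exp(−∫ k/Ḟ dF)`, integrated by cumulative trapezoid with
the unabsorbed survival mass reported explicitly; refolding distributions
integrate downward from a start force (default 35 pN, the upper end of the
reliable handle-model range).  Inverse-CDF sampling from these densities
drives the synthetic trace generator; a draw landing in the survival mass
becomes a no-event (censored) cycle.

## Tether model and trace analysis

The tether is two dsDNA handles in series with the protein: extensible
worm-like chain for DNA (`x = Lc(1 − ½√(kBT/FP) + F/S)`, defaults
P = 50 nm, Lc = 3400 nm for two 5-kbp handles, S = 1200 pN) and the Odijk
inextensible WLC for the polypeptide (P = 0.65 nm, 0.365 nm of contour per
residue, 15 nm of released linker in both states, 2.0 nm folded-domain
size, ΔLc = 31 aa × 0.365 nm released on unfolding).  Series elements
share the force, so extensions add; `invert_force` solves the monotone
inverse to 10⁻⁶ pN.  Model fits are restricted to 5–35 pN, where real
handles follow the eWLC before overstretching.

Rip detection is residual-based: the folded-state model predicts extension
from measured force; a rip is a jump in windowed (48-sample) median
residuals exceeding max(3.5 sigma of a locally estimated — rolling median
absolute difference — noise floor, 3 nm), with a force excursion against
the local ramp trend and a model-confirmation gate requiring the post-rip
samples to actually fit the target state.  The confirmation gate is what
suppresses the false positives that sustained force-noise excursions would
otherwise create, since those shift the residuals of both state models
together.  Detection starts at 8 pN: below that the folded/unfolded
extension separation (~5 nm) is inside the handle-compliance noise at the
default 0.5 pN force noise.  Candidate rip indices within ±3 samples of
the sharpest local step are each offered to the gates, which makes
detection robust to single-sample localisation error.  One event of each
kind per cycle is reported (a single two-state domain).

Contour-length changes are refined by fitting the protein contour
separately to the pre- and post-rip segments with every other parameter
fixed.  Two choices matter for accuracy at 0.5 pN force noise: the fit
minimises force-space residuals (measured force noise is homoscedastic,
whereas extension residuals inherit the ~5–50 nm/pN handle compliance),
and the 5–35 pN mask is applied to a median-smoothed force so that noise
at the mask boundaries does not select one-sided residuals (an effect
worth ~+1 aa of bias otherwise).  Recovered mean contour change on
synthetic data is within ~2% of the planted truth at default noise.

Group statistics are mean ± SEM with pairwise Mann–Whitney U tests: exact
enumeration for tie-free samples with n ≤ 20 per group, otherwise the
tie-corrected normal approximation without continuity correction (so
identical groups report p = 1).

## Synthetic data: what it emulates, what it does not

`make_toy_zincfinger` builds a deterministic 29-residue helix-hairpin fold
with two cysteines in the hairpin turn and two histidines on the helix
face mutually within 0.8 nm — the coordination geometry of a zinc finger —
plus basic residues giving the domain a net +4 charge.  It is a procedural
stand-in with the right size, topology and charge character, not a
homology model; a real Cα PDB can be substituted everywhere.

`simulate_trace` represents a pull-relax cycle as a commanded-extension
ramp; force follows the inverted series-tether model in the current state,
so unfolding produces the natural simultaneous extension-residual jump and
force drop.  Rupture and refolding forces are drawn by inverse CDF from
the ramp densities above.  Default kinetics k0 = 1e−4/s, x‡ = 1.0 nm,
ΔG‡ = 12 kBT (unfolding) and k0 = 5/s mirrored (refolding) with a
0.25 pN/s ramp put mean rupture forces at 26.8 pN and refolding at
19.2 pN, matching the experimentally familiar windows.  Gaussian noise
(0.5 pN, 1.0 nm) is added independently per sample; `zinc=False` drops the
per-cycle refolding probability to 17%.  Not emulated: instrument drift,
bead rotation, handle overstretching above ~35 pN, correlated trap noise,
dye photophysics beyond a single quench efficiency, and molecules that
stay unfolded across cycles (each pull starts folded).  Passing round-trip
tests therefore demonstrates correctness of the analysis pipeline under
the stated noise model, not robustness to every instrumental artefact.

`simulate_kymograph` renders donor fluorescence (quenched at ~20 Å
terminus separation against a 65 Å Förster radius, bright beyond 100 Å) as
a scanned-line image with two constant bead-autofluorescence bands and
Poisson counting noise.

## Numerical and degenerate-input conventions

Timestep validation against the bond-stability bound; blow-up abort at
1 nm/step.  WHAM raises on non-convergence with its last residual and on
non-overlapping windows, naming the gap.  `estimate_rate` refuses
all-censored inputs; a single event yields a point estimate with the CI
flagged degenerate.  `dhs_rate` raises at barrier vanishing.  Grids too
coarse to conserve rupture-density mass to 2% are rejected.  Empty FES
bins stay NaN.  All generators and stochastic estimators take explicit
seeds; identical seeds give bit-identical trajectories and files.

## Benchmark problem sizes

The shipped test-suite benchmarks run at deliberately small scale, chosen
so the full suite completes on one CPU in well under half an hour: rate
monotonicity uses 20 replicas × 4 forces on the free 29-bead domain with
2–6×10⁵-step trajectories; the in-tunnel folding comparison (L = 26 vs
L = 34, electrostatics on, 0.5 pN) uses 20 replicas of 1.5×10⁵-step
relaxation + 3×10⁵-step measurement; trace-pipeline checks use 100–200
synthetic cycles; the rupture-density oracle uses 10⁵ stochastic ramp
walkers.  At these sizes the in-tunnel comparison resolves the sign of the
electrostatic effect (the deep-linker construct folds no slower than the
mouth construct) but not its magnitude; its event counts per condition are
single digits, and the measured rates carry ~50% relative error.
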