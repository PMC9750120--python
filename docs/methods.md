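# Methods

## Model overview

`polyloopsim` simulates one chromosome as two coupled layers:

1. **A 1D lattice of loop extruders.** The chromosome is a row of
   monomers, each carrying `monomer_size_kb` (default 2 kb) of
   chromatinized DNA.  Loop extrusion factors (LEFs — cohesin- or
   condensin-like SMC complexes) bind as a pair of legs on adjacent
   monomers and translocate outward, enlarging a loop, until the LEF
   unbinds and the loop dissolves.  Boundary elements (CTCF-like sites)
   stall arriving legs direction-dependently with a per-attempt pass
   probability ("permeability").  Collisions between legs of different
   LEFs either block (impenetrable, cohesin-like) or are traversed
   freely (phantom / Z-loop, condensin-like).
2. **A 3D bead-spring homopolymer.** Each monomer is a 50 nm bead;
   consecutive beads are connected by springs, the chain has bending
   rigidity and hard-core excluded volume.  Each bound LEF adds a
   transient spring between its two leg monomers.

Snapshots of the coupled system yield virtual Hi-C contact maps,
virtual ChIP-seq tracks of LEF-leg occupancy, and optional three-way
contact counts; a chi-square layer compares maps against a reference,
optionally over a parameter grid.

## 1D kinetics (continuous time)

The 1D layer is sampled exactly (Gillespie): waiting times are
exponential in the total event rate, and one of

* bind (rate `k_bind` per unbound LEF),
* unbind (rate `unbind_rate_per_min` per bound LEF; both legs release
  instantly),
* leg step attempt (rate `velocity_kb_per_min / monomer_size_kb` per
  mobile leg)

is executed.  A step attempt onto a boundary site that blocks the
direction of motion succeeds with probability `permeability` per
attempt; a stalled leg simply retries at its stepping rate, which makes
"slowing down" quantitative.  Chain ends block permanently.  In
asymmetric mode, the translocating leg is chosen with equal probability
at binding and fixed until unbinding.

**Density parameterization.** Users specify the stationary mean number
of bound LEFs, `n_lef_target` (e.g. a 6 Mb chain at 1 bound LEF per
60 kb has `n_lef_target = 100`).  The pool holds `2 * n_lef_target`
LEFs and the per-LEF binding rate is
`k_unbind * n_target / (pool - n_target) = k_unbind`, so each LEF is
bound half the time and the mean bound count equals the target.  The
default unbinding rate is 1/20 min⁻¹ (a 20-minute residence time, the
order of magnitude reported by live-imaging studies of cohesin); it is
a documented, overridable default, not a fitted value.

**Validation.** For a single LEF on ≤ 12 sites the full state space
(unbound + all leg pairs, times the mobile-leg label in asymmetric
mode) is enumerated and the stationary distribution of the exact
transition-rate matrix is solved directly
(`lef_engine.exact_stationary_oracle`).  Boundary permeability enters
the oracle as an effective passage rate `step_rate * permeability`,
the thinned attempt process; stalled attempts are self-loops and do
not affect the stationary law.  The event engine is compared to this
oracle over all four extrusion/collision mode combinations and
permeabilities {0, 0.5, 1}.

A note on the statistics of that comparison: per-state z-scores
(batch-means standard errors, 50 batches of 800 min) are pivotal, so
with ~460 state comparisons a "every z below 3" assertion would fail
for a perfect engine about half the time.  The test therefore uses the
simultaneous form: per configuration, `sum(z^2) <= 2.5 K` over the
`K` states with stationary probability ≥ 5e-4 (the bound is the pilot
mean plus more than four pilot standard deviations, measured over 20
seeds disjoint from the pinned test seed; state-frequency correlations
make the spread wider than the independent-z value `sqrt(2K)`), plus
`z_max <= 6` as a gross localized-bias backstop and an absolute bound
of 0.005 on the unresolvable tail mass.

**Closed forms used as oracles.** With no boundaries and a dilute LEF,
the loop age at a stationary random time is exponential with mean
`1/k_off` (memoryless residence), and the loop grows at `2v`
(symmetric) or `v` (asymmetric), giving time-averaged loop lengths
`2 v / k_off` and `v / k_off`.  A two-state bind/unbind LEF spends a
fraction `k_bind / (k_bind + k_unbind)` of time bound.

## 3D chain and time coupling

The 3D layer is an off-lattice bead-spring chain evolved with
Metropolis single-bead moves (trial displacement uniform in a cube of
half-width `max_disp_nm = 10`):

* chain bonds: `bond_k (d - 50 nm)^2` with `bond_k = 0.02 kT/nm²`
  (bond-length s.d. ≈ 5 nm) and hard limits `[40, 75] nm`
  (0.8–1.5 bead diameters) — the hard range carries connectivity, the
  soft spring centers it;
* bending: `bend_k (1 - cos θ)` with `bend_k = 1 kT`, i.e. a
  persistence length of order one bead (50 nm), appropriate for a
  chromatin fiber at 2 kb/bead resolution;
* excluded volume: hard rejection below `0.8 *` bead diameter (40 nm);
* loop bonds: same spring as chain bonds but without the hard range, so
  a freshly advanced leg creates a momentarily stretched spring that
  subsequent sweeps contract — beads never teleport.

**Time mapping.** One MC sweep (n trial moves) represents
`1 / sweeps_per_min` minutes; the default `sweeps_per_min = 100` makes
loop capture fast compared to extrusion kinetics at the default
velocities while keeping desk-scale runs cheap.  The coupled run
alternates `advance_1d` over a coupling interval
(`min(0.1 min, snapshot_interval/10)` by default) with the
proportional number of sweeps, after a pure-polymer burn-in of
`equilibration_time_min`.  Because the underlying representation is an
equilibrium Monte Carlo chain, only equilibrium/contact statistics are
asserted; dynamic observables (MSD exponents, absolute relaxation
times) are not claims of this implementation.

**Equilibration honesty.** Full relaxation of a 3000-bead chain is not
reachable at desk scale; defaults burn in for a fixed, documented time
and the test suite checks radius-of-gyration-level observables only on
small chains where convergence was verified (e.g. the freely-jointed
`R²(s) = s⟨b²⟩` law on sub-chains).

## Observables

* **Contact maps.** Two monomers are in contact when closer than
  `contact_cutoff_nm` (default 100 nm = 2 bead diameters — the capture
  radius is a knob, not a fitted value).  Monomer contacts are pooled
  into bins of `hic_bin_kb` and normalized by
  `n_snapshots * |I| * |J|` monomer pairs per bin pair (distinct pairs
  within a bin); the diagonal is set to 1 by convention.  No iterative
  balancing is applied: model maps carry no experimental bias.
* **Virtual ChIP-seq.** Mean LEF legs per bin per snapshot; the track
  sums to twice the mean bound-LEF count.
* **Triplets.** All monomer triples with three pairwise contacts,
  binned; an optional per-snapshot cap subsamples uniformly and
  reweights by `total/cap` to stay unbiased.
* **Formats.** Maps are written as cooler-schema HDF5
  (chroms/bins/pixels/indexes, `symmetric-upper` pixel storage);
  tracks as 0-based half-open bedGraph.

## Chi-square comparison

The score is the mean over bin pairs in a genomic-distance band
(default: one bin to half the chain) of
`(scale * model_ij - ref_ij)^2 / sigma2_ij`, with `scale` the
least-squares alignment of the two mean contact-probability curves
P(s).  Variance choices:

* `replicates` — sample variance across per-replicate maps divided by
  the replicate count.  The replicate maps are an explicit argument:
  for a parameter-grid scan, pass the *reference's* replicates so the
  weights are identical across cells.  Weighting each candidate by its
  own replicate variance systematically favors high-variance cells
  (their scores are deflated), which inverts the argmin.
* `poisson` — `ref_ij / ref.n_snapshots`, the binomial variance of a
  probability estimated from n snapshots.
* `fixed` — user-supplied.

By default, variance estimates are **pooled across bin pairs at equal
genomic separation**: map noise is near-stationary per distance, and
per-pixel estimates from a handful of replicates are chi-square-noisy
(a near-empty reference pixel under Poisson weighting can contribute
thousands to the score by itself).  Per-pixel weighting remains
available (`pool_variance_by_distance=False`).  `chi2_score(A, A)` is
exactly 0.  The comparison band excludes the diagonal (uninformative)
and separations beyond half the chain (noise-dominated).

## Synthetic-data conditions and what they show

All tests run on synthetic chains the generator itself produces; the
study conditions mirror the framework's illustrative example where
feasible: symmetric extrusion, impenetrable collisions, uniform
loading, impermeable boundaries with 1:2 alternating spacing, 1 bound
LEF per 60 kb, 100 kb/min, 2 kb / 50 nm beads.  The 6 Mb / 3000-bead
chain is exercised arithmetically and for conformation-growth
invariants; TAD phenomenology is demonstrated on a 600 kb / 300-bead
chain (boundaries at beads 75 and 225 from the alternating-spacing
helper with gaps scaled to 150/300 kb), where ~3 h of simulated time
shows block-diagonal enrichment and a corner peak ranking first in its
distance band.  The parameter-recovery experiment uses a 100-bead
chain with a mid-chain boundary, 2-minute snapshots at
`k_off = 0.5 min⁻¹` (snapshots decorrelated by construction —
sampling faster than the loop turnover time makes every map
autocorrelation-dominated and recovery impossible at any grid
contrast), a 4-replicate × 250-snapshot reference and 3 × 200
candidates on a 3×3 grid of density × velocity.

What passing does *not* show about real data: no experimental noise
model (ligation artifacts, coverage bias, balancing), no epigenomic
heterogeneity of the fiber, single chromosome only, and no claim that
the default kinetic rates match any particular organism — they set a
self-consistent in-silico laboratory, and the comparison layer is the
tool for confronting it with real maps.

## Numerical choices and degenerate inputs

* Exact Gillespie sampling (no fixed-Δt sweep) keeps 1D rates
  unambiguous and oracle-comparable.
* Binding draws among admissible sites use rejection sampling with an
  exact-scan fallback, so the draw is uniform even on crowded lattices
  and a fully blocked lattice cleanly rejects (logged, state
  unchanged).
* Metropolis moves violating the hard bond range or excluded volume
  are rejected before any energy evaluation; `temperature -> 0`
  degenerates to pure descent.
* Snapshot emission times are `k * snapshot_interval_min`; a
  `sim_time 2 / interval 1` run emits exactly 2 snapshots.
* Seeds: replicate r of master seed s uses
  `SeedSequence(entropy=s, spawn_key=(r,))`; grid cell c uses
  `SeedSequence((s, c))` — platform-stable and collision-free.
  Worker-process scheduling cannot change results because replicates
  are written in index order.
* Degenerate configs (`n_lef_target = 0`, single loading site, gaps
  spanning the whole chain) reduce to the expected limits and are
  covered by tests.

## Known limitations

* The 3D move set is single-bead Metropolis; chain crossing is
  prevented only by excluded volume, and no hydrodynamics or
  confinement beyond an optional cubic box is modeled.
* The cooler writer emits the community HDF5 schema directly and
  round-trips through the package's own reader; float contact
  probabilities are stored in the `count` column.
* Replicate-variance estimates need ≥ 2 (practically ≥ 3) replicates;
  distance pooling assumes noise stationarity per separation, which
  holds for homopolymer-like maps but blurs pixel-level
  heteroscedasticity at strong corner peaks.
* One-sided "switching" extrusion, partial LEF-LEF traversal rates,
  and tension-dependent velocities are out of scope.
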