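# Methods

## The model

`ctdsim` simulates the transcription cycle of a single RNA polymerase II
(RNAPII) gene together with the phosphorylation dynamics of the
polymerase's C-terminal domain (CTD).  The CTD is a tail of tandem
Y1-S2-P3-T4-S5-P6-S7 heptad repeats (26 in budding yeast) whose serines
2, 5 and 7 are phosphorylated and dephosphorylated by a set of kinases
and phosphatases as the polymerase moves through the transcription
cycle.  The pattern of Ser2~P and Ser5~P along genes — high Ser5~P near
the promoter decaying over roughly the first 750 nt, Ser2~P rising to a
plateau around 1000 nt from the transcription start site (TSS) — is the
readout the model is built to explain mechanistically: the changes are
a function of the *time RNAPII spends in elongation*, which is the
window of opportunity for enzymes to act on the CTD.

The model is *rule-based*: agents (RNAPII, DNA, the enzymes) carry
named sites with internal states and bonds, and rules rewrite partial
patterns.  This avoids the combinatorial explosion of a species-based
formulation: with N DNA positions and two repeats of two modifiable
serines, a species-based model needs 16N species and 16·4·(N−1)
reactions (1280 and 5056 at N = 80; `species_expansion` constructs both
lists explicitly), whereas the rule-based model needs one rule per
mechanistic statement because phosphorylation rules apply independently
of the polymerase's DNA position.

### Structure

* **Gene geometry.** One DNA agent with a promoter region (activator,
  mediator, core promoter and TFIIH sites), 80 elongation sites e1..e80
  each representing a 30-nt polymerase footprint (2400 nt of coding
  sequence), and 20 maturation sites pA1..pA20.  At most one polymerase
  can bind a site, and a step to the next site requires it to be free:
  polymerases queue and cannot overtake (footprint exclusion).  An
  optional pause site turns that site's step into an exponential dwell
  with configurable mean (default 30 s), placed by coordinate (600 nt →
  site 21, the first site beginning after 600 nt; site i covers
  nt [(i−1)·30+1, i·30], TSS = nt 1, reported positions are site
  starts).
* **CTD representation.** Two representative heptad repeats (a, b),
  each with ser2/ser5/ser7 sites in state `u` or `p`.  Two repeats give
  three discrete phospho levels per mark (0, 1, 2), which is enough to
  estimate ensemble ratios; the engine supports more repeats if wanted.
  Serine sites are also binding sites: an enzyme docks (carrying the
  substrate specificity and the binding rate) and the modification
  happens on the release step.  Each serine site holds at most one
  enzyme at a time.
* **Contexts.**  The same enzyme acts differently at the promoter,
  during elongation, at the 3'-UTR and on free RNAPII.  Context is
  encoded structurally: promoter = RNAPII site `p` bound to the
  promoter; elongation = site `a` bound to an e-site with `e` free;
  3'-UTR = site `e` bound to a pA-site; free = no DNA bond.  Rules test
  these bonds (e.g. `RNAPII(e,a!_)` for elongation), so no rule can
  fire in a context it was not written for — this is asserted by
  constructing one witness mixture per context and checking each rule
  embeds only in its own.
* **Transcription cycle.**  Activator and Mediator assemble on the
  promoter; RNAPII joins only with a *fully unphosphorylated* CTD;
  TFIIH binds and its kinase Kin28 phosphorylates Ser5 and Ser7 of both
  repeats; the polymerase escapes to e1, capping the nascent transcript
  (a counter on RNAPII tracks transcript length, +30 nt per step).
  Srb10 competes with Kin28 for the same fully unphosphorylated
  promoter substrate at the slow binding tier and aborts initiation,
  returning a Ser5-phosphorylated polymerase to the free pool.  Entry
  into the 3'-UTR requires Pcf11, which binds elongating RNAPII only
  when at least one repeat carries Ser2~P — the gate that makes 3' end
  maturation Ser2~P-dependent; with no Ser2 kinases, polymerases pile
  up at the 3' end of the coding region and no transcript is ever
  released.  Rtt103 joins in the 3'-UTR; after the 20 maturation steps
  (a polyadenylation counter) the mature mRNA is released as a new
  agent and all factors are freed.
* **Phosphorylation rules** (all as bind/release pairs; binding at a
  p0-derived tier, release at p3):

  | enzyme | context | substrate | action | binding rate |
  |---|---|---|---|---|
  | Kin28 (TFIIH) | promoter | Ser5~U | Ser5~P + Ser7~P | fast (part of initiation) |
  | Srb10 | promoter, pre-TFIIH | all-U CTD | Ser5~P + abort | phosph2 = p0/10 |
  | Ctk1 | elongation | Ser2~U, Ser5~P | Ser2~P | phosph1 = p0/2 |
  | Bur1 | elongation | Ser2~U, Ser5~P | Ser2~P | phosph1 |
  | Ctk1 (variant) | elongation | Ser2~U, Ser5~U | Ser5~P | phosph1 |
  | Rtr1 | elongation | Ser5~P (any Ser2) | Ser5~U | rtr1_bind_multiplier × phosph1 |
  | Fcp1 | elongation | Ser2~P | Ser2~U | phosph1 |
  | Ssu72 | 3'-UTR | Ser5~P / Ser7~P | to U | phosph0 = p0 |
  | Fcp1 | free (recycling) | Ser2~P / Ser5~P | to U | phosph0 |
  | (lumped) | free | Ser7~P | Ser7~U | phosph2 |

  The Ctk1 Ser5-kinase activity is the model's variant axis
  (`ctk1_ser5_variant`): `NONE`, `FROM_UU` (from the doubly
  unphosphorylated substrate; the default retained in the model),
  `FROM_PU` (from Ser2~P, Ser5~U) or `BOTH`.  The `FROM_UU` pair is
  named `binds1/binds2` and `release1/release2` and renders verbatim in
  the rule listing; Ser5 is phosphorylated on release.  Rtr1's binding
  rate relative to the Ser2 kinases is the second comparison axis
  (multiplier 2.0 / 1.0 / 0.5, default 2.0, i.e. Rtr1 binds at p0 and
  the Ser2 kinases at p0/2): Rtr1 outcompeting the Ser2 kinases for
  the Ser5~P substrate is what shapes the Ser5→Ser2 transition.
  The slow Ser7~P cleanup on free RNAPII is a lumped housekeeping
  reaction: without it, polymerases escaping the 3'-UTR with residual
  Ser7~P could never re-initiate (initiation requires the all-U CTD)
  and the free pool would be slowly sequestered.  No rule in the
  elongation context touches Ser7, so the Ser7~P ratio is constant
  along the coding region by construction.

## The engine

A minimal site-graph rewriting engine with the exact Gillespie direct
method.  A rule's propensity is its stochastic rate constant times the
number of embeddings (injective, constraint-satisfying maps) of its
left pattern into the mixture; embeddings of symmetric patterns are
counted per ordering (no automorphism division — the CTD model has no
rule with two identical left-hand agents, so this convention is
observationally irrelevant here and is simply documented for reuse).
Pattern sites support state tests, unbound / bound-to-anything /
shared-label bond tests, and integer counter tests; rules may create
and delete agents and update counters.

Matching is recomputed per event, with two exactness-preserving
optimisations: per-signature candidate indexing, and dirty-rule
invalidation keyed on (agent type, site) so only rules whose footprint
overlaps the sites touched by an event are re-matched.  A bond that is
swapped in a single rule application (a polymerase stepping from e_i to
e_{i+1} rebinds the same site) leaves bound-status tests unaffected and
does not invalidate them.  These caches cannot change trajectories:
the per-trajectory PCG64 generator (`numpy.random.default_rng(seed)`)
consumes exactly three uniforms per event — waiting time, rule choice,
embedding choice — so runs are bit-reproducible given the seed,
regardless of caching.  Ensembles use seeds `base_seed + i`.

Observables are sampled on a user-supplied time grid (value = state
after the last event at or before each time), which keeps ensemble
averages on aligned grids.  A validation mode re-checks bond symmetry
and single-site occupancy after events.  For models whose reachable
state space is small, `enumerate_ctmc` constructs the full generator
matrix by breadth-first search so the sampler can be checked against
the matrix exponential; the test suite additionally checks against
hand-written generators and closed forms so the oracle does not share
the matching code path.

## Readouts

* **Metagene profile**: per-site RNAPII density (mean occupancy) and
  the per-mark ratio of phosphorylated repeats to repeats present,
  computed per occupied observation and averaged — the per-polymerase
  reading of a ChIP ratio track.  Ratios are undefined (NaN) at sites
  never observed occupied.
* **Steady-state window**: each run's sampling window opens at its 5th
  mature-transcript release and closes 50 release cycles later (capped
  at the run end).  The long window is deliberate: the settling
  estimator below needs per-site Monte-Carlo errors of a few times
  10⁻³, which a 10-cycle window would not deliver at practical
  ensemble sizes.
* **Settling position**: the plateau is the mean of the channel over
  the last 10 elongation sites; the band is 5% of the channel's
  maximum deviation from the plateau; the settling position is the
  start coordinate of the first site from which the channel stays
  inside the band.  Because an all-later-sites criterion on a noisy
  curve is decided by its last random excursion, the profile is first
  denoised by least-squares projection onto c₀ + c₁e^(−x/λ₁) +
  c₂e^(−x/λ₂) (length scales on a log grid): the relaxation of the
  per-repeat phospho-state chain in elongation time is exactly a
  mixture of exponentials in position, so this projection removes
  noise without biasing the shape.  A running-median alternative and
  the raw curve are available through the `smooth` parameter.
* **Amplicon readout**: occupancy and phospho counts summed over the
  sites each named amplicon overlaps, ensemble-averaged per time point
  and normalized to the same quantity at a reference time.  Series
  with zero reference signal are flagged undefined rather than
  divided.  Since the simulated gene is empty at induction (t = 0),
  drivers default the normalization reference to the first sampled
  post-induction time point rather than t = 0.  Exact amplicon
  coordinates of the emulated reporter are not fixed by the construct;
  the defaults tile the gene (promoter, exon 1, around the pause /
  3' splice site, and the two ends of exon 2) and are configurable.
* **Threshold-and-scale fit**: measured ≈ scale·max(model − floor, 0) +
  offset, floor searched over a coarse grid of model quantiles with
  (scale, offset) in closed form per floor.  A constant model vector
  degenerates to an offset-only fit and is flagged.  A configurable
  3x3 antibody cross-reactivity matrix (`apply_cross_reactivity`) maps
  true (Ser2~P, Ser5~P, Ser7~P) ratios to observed signals; the
  default is the identity (ideal mark-specific antibodies) because no
  measured weights are bundled.

## Calibration

The phosphorylation tiers are fixed at the reference values p0 = 0.1/s
and p3 = 100/s.  The remaining rates and copy numbers are not
measured quantities; they were calibrated — once, before the test
outcomes were inspected — against three observable targets: a mature
mRNA every ~4 s at steady state, Ser5~P settling ~750 nt from the TSS,
and Ser2~P plateauing ~1000 nt.  The procedure is reproducible with
`scripts/calibrate.py`:

1. A per-repeat 4-state chain over (Ser2, Ser5) in the elongation
   context (effective rate of each conversion = binding tier × enzyme
   copies, since release at p3 is never limiting), averaged over the
   Erlang age distribution a polymerase has at each site, screens
   enzyme copy numbers for the right Ser2:Ser5 settling-position ratio
   and steady-state ratio levels.
2. Direct ensemble simulation under the same settling estimator as the
   analysis code refines the elongation step rate and promoter-loading
   rate.

Shipped defaults: Rtr1 6, Ctk1 7, Bur1 1, Fcp1 1, Ssu72 5, Srb10 2
copies; 20 RNAPII (Little's law: ~0.25/s flux × ~45 s residence keeps
~11 polymerases in flight, so a smaller pool starves initiation);
elongation and maturation step rate 2.36 sites/s (≈ 71 nt/s — fast for
yeast averages but within the range of processive elongation, and the
value that places both settling targets); RNAPII promoter loading
0.056/s per free fully-recycled polymerase.  Two features of this
point deserve comment.  First, Rtr1's effective activity is high
relative to the Ser2 kinases — which is exactly the regulatory logic
the model encodes (Rtr1 removes the Ser2 kinases' preferred substrate,
so most repeats arrive at the Ser2-kinase step only transiently).
Second, Fcp1's slow elongation-phase turnover of Ser2~P is what sets
the long ~1000-nt approach of the Ser2~P channel and keeps it
*monotone*: a faster Fcp1 produces a transient Ser2~P overshoot whose
slow relaxation both breaks the monotone rise and makes the settling
position ill-conditioned.  The resulting steady-state plateau ratios
are Ser2~P ≈ 0.68 and Ser5~P ≈ 0.14 per repeat with occupancy ≈ 0.07
per site.  Because effective rates are binding-tier × copies, the copy
numbers and p0 trade off exactly and only their products are
identified by the targets.

## What the synthetic data emulate — and what they do not

No external data are read.  The fixture generator produces "measured"
profiles with the qualitative shapes of CTD metagene data (exponential
Ser5~P decay, saturating Ser2~P rise, flat Ser7~P, Gaussian noise,
clipped at zero) for exercising the threshold-and-scale fit; variant
comparisons against such fixtures (or against profiles generated by
the model itself, as in the self-consistency test) demonstrate that
the machinery discriminates the variants, *not* that any variant fits
real genome-wide ChIP data.  Real ChIP signal differs in ways the
fixtures do not emulate: antibody cross-reactivity, background and
input normalization, shearing resolution well below 30 nt, and
gene-to-gene heterogeneity in a metagene average (the simulation
averages stochastic runs of one gene instead).  Conclusions about real
data therefore rest on the original experiments, not on these tests.

## Numerical and design choices

* Exact SSA, no tau-leaping; mixtures here hold ~100 agents and
  ~150 rules, and a steady-state run of 240 s simulated time costs
  well under a second of CPU.
* Ensemble sizes: 200–500 runs for profile estimates (standard errors
  of a few 10⁻³ per site), 10 runs pooling ≥200 release intervals for
  the synthesis rate, 200 seed-paired runs per arm for the pause
  contrast.  Sizes are stated per driver and are parameters, chosen to
  put Monte-Carlo error comfortably below the effect sizes asserted.
* Paired designs share seeds between arms (pause/control, variant
  cells) so contrasts are not diluted by between-run variance.
* Direction-only claims are tested with one-sided Mann–Whitney tests
  at α = 0.01; the p3-invariance claim uses Kruskal–Wallis across p3
  groups at fixed p0.  These test choices are this package's own
  operationalization of qualitative statements.
* Degenerate inputs: zero-propensity models terminate early and pad
  the observable grid with the final state; empty sampling windows,
  amplicons beyond the gene, non-positive rates, unknown configuration
  keys and malformed profile cells raise typed errors.

## Known limitations

* Two heptad repeats, not 26: ratios take values in {0, ½, 1} per
  polymerase and repeat-to-repeat cooperativity cannot be represented.
* Srb10's abort mechanism and the Ser7~P cleanup on free RNAPII are
  minimal placeholders for mechanisms the literature leaves open.
* The Kappa text format is not parsed; models are built
  programmatically and rendered to Kappa-like text for inspection.
* Copy numbers and unprinted rates are calibrated, not measured;
  only their products with the binding tiers are identified.
* Performance targets a single gene; the engine recomputes matches per
  event and is not meant for genome-scale mixtures.
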