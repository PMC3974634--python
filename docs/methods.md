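# Methods

## The system being modelled

A gene-targeting vector carries a selection cassette (NEO) flanked by two
homology arms matching the chromosomal locus (the canonical example is
disruption of *HPRT* exon 3, where G418 selects for cassette integration
and 6-thioguanine for loss of HPRT function, separating targeted clones
from random integrants). Each arm is marked with vector-specific SNPs
that create restriction sites plus one small hairpin insertion, so
sequencing or digestion of a targeted clone reports, marker by marker,
whether the viral or the chromosomal allele was kept. Marker positions
are 1-based bp measured outward from each arm's junction with the
cassette; the cassette is treated as a point, since recombination
geometry only needs to know whether a tract covers it. Signed
coordinates are negative on the left arm, positive on the right.

The default map uses 1000-bp arms with markers (inner → outer) AseI 300,
NcoI 547, LHP 650, EcoRI 800, NdeI 950 on the left and SspI 130, SacI
261, RHP 400, XbaI 600, SbfI 800 on the right. NcoI (−547) and SacI
(+261), and the nuclease knock-in positions −569/+266, are the
positions the marker roster fixes; the others are package fixture
choices consistent with the published inner-to-outer ordering and are
fully configurable through `MarkerMap` or the map config file.

## Mechanism models

All mechanisms share one geometric assumption: crossover /
Holliday-junction resolution positions are **uniform** over the homology
available to them. This is the model a linear retention gradient
identifies — the observed profiles are linear, not exponential, so no
tract-length or branch-migration term is included by default.

**Ends-out DSBR.** Per arm, two strand crossovers
`x_top, x_bot ~ U(0, L)` i.i.d. bound the heteroduplex.

* *SEGREGANT mode* (a clone picked after the heteroduplex has
  segregated): one strand per arm is chosen at random; a marker at
  distance `d` is viral iff `d < x`. Marginal retention: `1 − d/L`.
* *COLONY mode* (a colony grown in situ, both daughters present): a
  marker is `V` below `min(x_top, x_bot)`, `S` (sectored) between, `C`
  beyond. The two daughter genotypes are paired in **trans**: the
  daughter with the longer viral tract on the left arm carries the
  shorter one on the right, because the two arms' heteroduplexes sit on
  complementary strands of one intermediate.

The joint law of the two crossovers is not observable from marginal
retention; an alternative `FIXED_TRACT` law (second crossover a constant
span outward from the first, clipped at the arm end) is exposed through
`SimParams.crossover_law` but off by default.

**Single-strand assimilation.** One annealed strand per arm, a single
crossover `~ U(0, L)`; the non-assimilated daughter lacks the cassette
and dies under selection. Identical marginal retention to a segregant,
but colonies are never sectored — which is exactly how the sectoring
assay separates the two mechanisms.

**Ends-in (DSB-induced).** A chromosomal DSB at position `s` on one arm
reverses the polarity: the broken chromosome ends invade the vector.
With probability `p_alt` the event follows the ALT pathway (SDSA or HJ
dissolution — identical marker signatures, so they are merged); else
DSBR:

* *DSBR*: distal resolution `y ~ U(s, L)` on the DSB arm; proximal
  resolution `p` uniform over the remaining homology (signed
  `U(−L_other, s)`). Selection keeps only events whose conversion tract
  covers the cassette (`p < 0` for a right-arm DSB); markers strictly
  between `p` and `y` are viral. Hence every marker between cassette and
  DSB is retained in exactly 100% of surviving clones, and a marker at
  `d > s` is retained with `(L − d)/(L − s)`.
* *ALT*: the chromosome copies the vector exactly up to the break — one
  half of the nuclease site is retained (`half_site_present`), markers
  inside `s` are viral, every marker distal to `s` is lost; the far arm
  uses the DSBR proximal law conditioned on covering the cassette
  (an ALT clone without the cassette would not survive selection).

`p_alt` is defined as the pathway fraction **among selection-surviving
clones** — the quantity a genotyped clone panel actually measures — not
per attempted event; the default 0.17 is the observed minor-pattern
fraction. The DSBR selection filter still shows up in the reported
attempt count.

**Random integration.** The vector inserts elsewhere with intact arms:
every marker viral in every clone. A flat 100% profile is thus the
random-integration signature, trivially separable from any targeting
mechanism.

**Double-event mixture.** With probability `1 − q` a colony is one
ends-out COLONY event (trans by construction); with probability `q` it
is two independent single-crossover genotypes sharing one colony. For
double events, which daughter carries the viral tract is independent
between arms, so cis and trans each arise with probability ½ — giving
`p_trans = 1 − q/2` among both-arm-sectored colonies and the estimator
`q = 2(1 − p_trans)`. Both colony types have the same per-arm sectoring
probability (two i.i.d. uniforms either side), so conditioning on
"sectored on both arms" does not bias the estimator.

## Mismatch-repair anti-recombination

Each of the `m` vector/chromosome mismatches independently triggers
abortion of the recombination intermediate with probability `r`, so an
event survives MMR with `(1 − r)^m`. Rejection is event-level: it
rescales efficiency (the attempts counter) and leaves tract geometry
untouched, which reproduces the empirical invariance of retention
profiles to MMR status. `calibrate_rejection` inverts an observed
efficiency ratio of two vectors differing only in `m`: for the 7.5-fold
ratio between 2- and 15-mismatch vectors, `r = 1 − 7.5^(−1/13) ≈ 0.144`.

An MMR-proficient (MLH1⁺) host suppresses efficiency by a further single
multiplicative factor, default 50 — the printed lower bound of the
observed effect. A per-mismatch proficient-host model was rejected
because one per-mismatch factor cannot give the *same* ≥50-fold
suppression for both a 2- and a 15-mismatch vector.

Tract "spell-checking" (patching of individual heteroduplex mismatches
before mitosis) is available as an optional post-processor
(`spell_check_heteroduplex`), off by default, with hairpin markers
exempt since hairpin loops are refractory to mismatch recognition.

## Sampling and numerical choices

* **Rejection sampling without materialisation.** Tract geometry is
  independent of the MMR veto, and the accepted ends-in proximal point
  has a known conditional law (`U(−L_other, 0)`), so simulators draw
  accepted geometry directly and sample the attempt count from its exact
  negative-binomial law. The emitted tables are distributionally
  identical to literal redraw loops, at vectorised cost.
* **Fits.** Linear retention fits are OLS of frequency on unsigned
  distance, per arm, unweighted by default (an inverse-binomial-variance
  weighted option exists). The exponential model `A·exp(−k·d)` is fitted
  by `scipy.optimize.curve_fit`, initialised from a log-linear fit on
  positive frequencies; its R² is computed about the mean, like the
  linear one, so the two are comparable, and model preference is by
  lower RSS with ties to linear. Markers with no usable calls (`n_total
  = 0`) are excluded; fits require ≥3 points per arm.
* **Sectored markers count as retained** in profiles by default (an `S`
  colony demonstrably carries the viral allele); a flag flips this.
  Hairpins are ordinary binary markers for retention and regression but
  carry a kind tag so the spell-check exemption can find them.
* **Trans/cis calls** require reciprocal subclones at every
  parent-sectored marker and within-arm agreement on which subclone is
  viral; any violation — possible only with injected genotyping noise —
  returns AMBIGUOUS with a reason rather than a forced call. The
  double-event fraction carries an exact Clopper-Pearson interval
  propagated through `q = 2(1 − p)`.
* **Degenerate inputs.** Validators return violation lists (never
  throw); parsers raise errors naming the file line; probability
  parameters are range-checked at construction. A DSB must lie strictly
  inside its arm; a marker exactly at `d = L` is legal and retained with
  probability 0.

## What the synthetic data does and does not emulate

The generators reproduce the *design* of per-clone genotype panels:
marker maps of the published geometry, drug-selected clone counts of
order 10–250 (the profile experiments use n = 230, plateau experiments
n ≈ 48–64, subcloning n = 11 colonies), mechanism mixtures, genotyping
error and missingness injected post hoc (`add_noise`), never inside the
mechanism models — so the mechanistic oracles stay exact. They do not
emulate chromatograms, partial restriction digests, doublet colonies
from plating artifacts (beyond the double-event mixture), absolute
targeting frequencies per cell, or DSB induction kinetics. Passing tests
therefore validate the internal consistency of the mechanism models and
estimators, not wet-lab error modes beyond the simple noise model.

## Problem sizes

Closed-form oracle checks run at 10⁵ clones (binomial 3σ tolerances);
monotonicity at 10⁴; mixture round trips at 5×10³ colonies; the
linearity sweep uses 100 seeds × 230 clones; Monte-Carlo MMR ratios use
10⁵ events per vector and 10⁶ per host condition (host-ratio counts are
small in the proficient arm, so the larger sample keeps the ratio's
relative error near 2%). The full suite runs in well under a minute on
one core.

## Known limitations

* The cassette has no internal coordinates, so "resolution inside the
  cassette" is not representable; events either cover it or not.
* One `r_reject` serves the MMR-reduced reference host; residual-repair
  differences between partially deficient lines are not separated.
* The ends-in proximal-resolution law (signed-uniform across cassette
  plus far arm) reproduces the observed far-arm linear gradient but is
  an assumption; no published measurement pins the joint law.
* True homology-arm lengths and the six unpublished marker positions are
  fixture values; all downstream statistics are parametric in the map,
  so swapping in a measured map is a one-file change.
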