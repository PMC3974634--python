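# hrtract

Mechanistic simulation and analysis of marker-retention tracts in human
gene targeting.

When a targeting vector (for example an rAAV carrying a drug-resistance
cassette flanked by two homology arms) recombines with its chromosomal
locus, the positions at which recombination intermediates are resolved
decide which vector-specific markers — restriction-site SNPs and small
hairpins placed along the arms — end up in the targeted clone. The
per-marker **retention frequency** plotted against marker distance from
the cassette is therefore a readout of the recombination mechanism, and
different mechanisms make sharply different predictions:

| mechanism | retention profile | colony sectoring |
|---|---|---|
| ends-out double-HJ repair (DSBR) | linear, `P(retain) = 1 − d/L` | sectored, *trans* across arms |
| single-strand assimilation | same linear marginal | never sectored |
| ends-in DSBR (chromosomal DSB at `s`) | 100% plateau for `d < s`, then `(L−d)/(L−s)` | — |
| SDSA / HJ dissolution (ends-in ALT) | half nuclease site kept, all distal markers lost | — |
| random integration | 100% everywhere | never sectored |

`hrtract` provides forward simulators for each mechanism (uniformly
distributed crossover/HJ-resolution positions over the homology, drug
selection as a hard filter, event-level mismatch-repair rejection
`1 − (1−r)^m`) and the analysis pipeline that discriminates them from
per-clone genotype tables: retention profiles with per-arm linear and
exponential fits, sectored-colony and trans/cis subclone classification,
the double-event fraction estimator `q = 2(1 − p_trans)`, DSBR-vs-ALT
pathway calls, and mismatch-repair calibration
`r = 1 − ratio^(−1/(m_large − m_small))`.

It is aimed at people modelling gene-targeting or gene-editing outcomes
who want a tested, seedable generator of realistic clone-genotype tables
and the statistics to interpret them.

## Worked example

Simulate 230 drug-selected ends-out clones on the default 10-marker map
(two 1000-bp arms, 4 SNPs + 1 hairpin each) and fit the retention
gradient:

```text
$ hrtract simulate --mechanism ends_out --n 230 --seed 1 --out clones.tsv
wrote 230 clones to clones.tsv
$ hrtract analyze-retention --table clones.tsv --compare
LEFT arm: slope=-0.000973/bp intercept=0.9464 R^2=0.9885 (5 markers)
LEFT arm: preferred=LINEAR delta_RSS(exp-lin)=0.00499
RIGHT arm: slope=-0.001003/bp intercept=1.0136 R^2=0.9972 (5 markers)
RIGHT arm: preferred=LINEAR delta_RSS(exp-lin)=0.00538
```

The fitted slopes sit at the theoretical `−1/L = −0.001` per bp, the
intercepts at 1 (every clone keeps the cassette-adjacent sequence), and
R² is near unity on both arms — the linear gradient that identifies
uniformly distributed crossover resolution. Model comparison prefers the
linear over the exponential fit on both arms.

Calibrating mismatch-repair rejection from a 7.5-fold efficiency ratio
between a 2-mismatch and a 15-mismatch vector:

```text
$ hrtract calibrate-mmr --ratio 7.5 --m-large 15 --m-small 2
r_reject = 0.1436
relative efficiency m=2 DEFICIENT: 0.733458
relative efficiency m=15 DEFICIENT: 0.0977944
...
```

i.e. each mismatch independently vetoes ~14% of events, and the same
model predicts the efficiencies of both vectors in MMR-deficient and
MMR-proficient (50-fold suppressed) hosts.

The same operations are available as library calls
(`hrtract.simulate_ends_out`, `hrtract.retention_profile`,
`hrtract.fit_retention_model`, ...); see the module docstrings and
`docs/methods.md` for the model details.

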