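# hiffl

Tools for studying how **cycling (oscillatory) hypoxia** can drive gene
expression that neither normoxia nor stable hypoxia produces, through
**incoherent feed-forward loops (IFFLs)** rooted at the hypoxia master
regulator **HIF-1**.

Solid tumors frequently experience fluctuating oxygen: regions cycle
between hypoxia and reoxygenation on a timescale of hours. Most genes
respond to such cycling with an expression level *between* their
normoxic (N) and stably hypoxic (H) levels — a time-averaged dose
response. A reproducible minority instead shows *oscillation-specific*
expression: higher or lower under cycling hypoxia (O) than under either
steady condition. This package implements the modelling and analysis
pipeline for explaining those patterns with three-node IFFLs in which
HIF-1 regulates a target gene directly and, with opposite net sign,
through an intermediary transcription factor (TF) such as p53 or
Notch1. It is aimed at systems-biology and cancer-biology groups who
want to simulate such circuits, map their parameter regimes, and screen
their own differential-expression data for candidate loops.

## The model

HIF is a prescribed dimensionless input (0 = normoxia, 1 = hypoxia;
cycling hypoxia is a square wave of 1 h at 1 followed by 0.5 h at 0).
For the type 3 loop (HIF → TF →  Target activating, HIF ⊣ Target) the
dynamics are

```
dTF/dt     = β_TF · (HIF/K_H)^N / (1 + (HIF/K_H)^N)  −  α_TF · TF

dTarget/dt = β_T · [ (TF/K_TF)^N / (1 + (TF/K_TF)^N) + A ] · 1/(1 + (HIF/K_H)^N)
             − α_T · Target                                     (multiplicative)

dTarget/dt = β_T · [ (TF/K_TF)^N / (1 + (TF/K_TF)^N) + A/(1 + (HIF/K_H)^N) ]
             − α_T · Target                                     (additive)
```

with Hill coefficient `N`, dissociation constants `K_H`, `K_TF`, and a
TF-independent activation weight `A`. The other three IFFL types
replace each Hill term by its activating/repressing form according to
the loop's sign triple (X→Y, Y→Z, X→Z): type 1 (+,−,+), type 2
(−,−,−), type 3 (+,+,−), type 4 (−,+,+). A circuit is simulated through
a sequential protocol — normoxia on t ∈ [−15, 0), stable hypoxia on
[0, 15), cycling hypoxia on [15, 30) — and the Target mean over the
final 9 time units of each condition window is ordered to yield one of
six labels (`H<O<N`, `N<O<H`, plus the four oscillation-specific ones:
`H<N<O`, `N<H<O`, `O<H<N`, `O<N<H`).

The package also contains:

* `hiffl.circuits` — signed feed-forward-loop taxonomy, enumeration of
  all loops rooted at a master regulator over a TRRUST-style edge list,
  and a coherence/type census;
* `hiffl.phase` — (K_H, K_TF) sweeps and phase diagrams of the ordering
  labels;
* `hiffl.patterns` — classification of genes into N/H/O orderings from
  DE contrast tables (any DE engine; the reference workflow is DESeq2),
  knockdown-disruption calls, TF regulatory-sign inference, and
  assembly of putative HIF-1 loops;
* `hiffl.synth` — a negative-binomial generator for the 3 genotypes ×
  3 oxygen conditions × 3 replicates design with planted patterns and
  planted TF dependence, plus a stand-in DE test for closed-loop use;
* a `hiffl` command-line interface over all stages.

## Worked example

```python
from hiffl import CircuitSpec, simulate, condition_means, classify_order

spec = CircuitSpec(iffl_type=3, mode="additive").with_params(k_h=0.01, k_tf=0.219)
traj = simulate(spec)          # sequential N -> H -> O protocol, 901 samples
summary = condition_means(traj)
print(summary)
print(classify_order(summary))
```

prints

```
ConditionSummary(mean_n=0.9997314434263517, mean_h=0.9893794574594356, mean_o=1.2947113034538225)
OrderPattern(label='H<N<O')
```

i.e. at this (K_H, K_TF) the target is *highest under cycling hypoxia*
(mean 1.295 in arbitrary units) even though stable hypoxia slightly
*lowers* it relative to normoxia (0.989 vs 1.000) — an
oscillation-specific `H<N<O` pattern that no averaged dose response can
produce. The same circuit family responds to intermediate steady
signal, too:

```console
$ hiffl steady-state --type 1 --mode additive --kh 0.638 --ktf 0.534
HIF=0        TF*=0         Target*=1
HIF=0.666667 TF*=0.532916  Target*=1.03444
HIF=1        TF*=0.793844  Target*=1.0272
```

the steady-state target at the square wave's duty-cycle mean (HIF =
2/3) exceeds both the normoxic and the fully hypoxic fixed points.

Phase diagrams and the transcriptomic stages run the same way:

```sh
hiffl phase-diagram --type 3 --mode additive --grid-points 20 --out pd.tsv
hiffl run --stages synth,de,classify,infer --out-dir demo/
```

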