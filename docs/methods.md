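# Methods

## Circuit model

Each circuit has one prescribed input (HIF, the dimensionless activity
of HIF-1: 0 in normoxia, 1 in hypoxia) and two dynamic species, the
intermediary transcription factor TF and the Target gene product, both
in arbitrary concentration units. Transcriptional regulation is
modelled with Hill functions sharing one cooperativity exponent
`n_hill`; activation uses `u/(1+u)` and repression its complement
`1/(1+u)` with `u = (x/k)^n`. The two HIF-facing edges (HIF→TF and
HIF→Target) share the dissociation constant `k_h`; the TF→Target edge
uses `k_tf`. Degradation is first-order.

The four incoherent loop types are encoded by their sign triples
(X→Y, Y→Z, X→Z): 1 = (+,−,+), 2 = (−,−,−), 3 = (+,+,−), 4 = (−,+,+).
The TF equation applies the X→Y Hill form to HIF. Target production
combines the indirect term `f_ind` (Y→Z Hill form of TF) and the direct
term `f_dir` (X→Z Hill form of HIF) in one of two modes:

* **multiplicative** — `β_T (f_ind + A) · f_dir`: the direct HIF
  element gates the whole promoter (transcriptional synergy, e.g. a
  silencer looping over the locus);
* **additive** — `β_T (f_ind + A · f_dir)`: the direct element is an
  independent enhancer/silencer of weight `A` (`a_target`).

For the type 3 loop these reduce exactly to the canonical
activator+repressor equations quoted in the README. The generalization
to types 1, 2 and 4 replaces each term by the form dictated by the sign
triple, keeping the same `k_h` for both HIF-facing edges — the minimal
extension that preserves the type 3 special case.

### Assumptions

Deterministic mass-action/Hill kinetics; no transcription–translation
delay, no stochasticity, no spatial structure, no feedback from Target
or TF onto HIF. HIF itself is an input, not a dynamic species (but see
the continuous-HIF option below).

## Input protocol and condition windows

Time is in hours. The reference protocol is sequential within one
simulation: normoxia (HIF = 0) on [−15, 0), stable hypoxia (HIF = 1) on
[0, 15), cycling hypoxia on [15, 30) as a square wave of 1 h at 1
followed by 0.5 h at 0 (period 1.5 h, duty-cycle mean 2/3, hypoxic
phase first). Intervals are closed on the left, open on the right, so
the signal is right-continuous at switches. Initial TF and Target are
zero. Output is sampled on a uniform grid of step 0.05 (901 points).

Condition means are taken over the final 9 time units of each window —
(−9, 0] for N, (6, 15] for H, (21, 30] for O — using half-open
membership on the output grid, from the one continuous trajectory (the
sequential design means the H and O windows inherit their preceding
history; the 6-unit lead-in before each averaging window lets the
fast-relaxing baseline circuits settle).

## Ordering classification

The three window means are sorted into a strict label (`H<N<O` means
hypoxia lowest, cycling highest). A label is only emitted when every
pairwise gap exceeds `rel_tol` × (largest mean), with `rel_tol = 1e-3`
by default; otherwise the cell is `UNRESOLVED`. Ties are therefore
surfaced, never forced into a pattern. The four labels that place O
outside the [N, H] range (`H<N<O`, `N<H<O`, `O<H<N`, `O<N<H`) are
*oscillation-specific*: a monotone response to the time-averaged input
cannot produce them. Classification is scale-invariant.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `beta_tf`, `beta_target` | max production rates | conc/h | 1 |
| `alpha_tf`, `alpha_target` | degradation rates | 1/h | 1 |
| `k_h` | HIF dissociation constant | — | 0.5 (swept 0.01–2) |
| `k_tf` | TF dissociation constant | — | 0.5 (swept 0.01–2) |
| `n_hill` | Hill cooperativity | — | 3 |
| `a_target` | TF-independent activation weight | — | 1.0 |

Rates of 1 make the relaxation timescale 1 h, commensurate with the
1.5 h forcing period — the regime where the two arms' different
response times matter. The sweep range [0.01, 2] spans from
essentially-constitutive to barely-responsive edges while keeping the
Hill terms well-conditioned; 20 evenly spaced grid points include both
endpoints. `n_hill` and `a_target` were fixed by scanning small integer
cooperativities and basal weights on the baseline grid for the richest
qualitative behavior: at `n_hill = 3`, `a_target = 1` every one of the
six orderings is realizable in both inhibition modes of the type 3
loop, the additive mode shows all four oscillation-specific patterns,
and types 1, 2 and 4 retain oscillation-specific regimes. At weaker
cooperativity or smaller basal weight parts of this repertoire
disappear (e.g. `n = 2`, `A = 0.5` loses `H<N<O` in the additive type 3
diagram), so the defaults sit deliberately inside the interesting
regime. Both are configurable, and the phase-diagram *claims* in the
test suite are defaults-dependent in exactly this sense.

## Numerics

Integration uses an error-controlled Runge–Kutta method
(`scipy.integrate.solve_ivp`, RK45, rtol 1e-8 / atol 1e-10), restarted
at every input discontinuity — segment boundaries and every square-wave
switch — so no step ever straddles a jump. Phase-diagram sweeps
integrate all grid cells jointly as one vectorized ODE system; this is
evaluation-order-invariant and is cross-checked against per-cell runs
in the tests. States that undershoot below −1e-9 would be clipped to
zero with a warning; in practice trajectories stay nonnegative.
Fidelity is verified two ways: against closed-form steady states under
constant input (≤ 1e-4 relative at t = 50) and against an independent
fixed-step RK4 reference (dt = 1e-3) on the full sequential protocol
(≤ 1e-3 max absolute error; observed ~1e-8).

Steady states are closed-form: `TF* = (β_TF/α_TF) f_xy(HIF)` inserted
into the mode's production law. `response_curve` flags a parameter set
non-monotonic when an interior HIF level's `Target*` exceeds (or
undercuts) both endpoint values by more than `rel_tol` (default 1e-6)
times the curve maximum — the steady-state route to
oscillation-specific behavior, since a circuit tuned to intermediate
signal responds to the duty-cycle mean (2/3) rather than to either
extreme.

## Continuous HIF dynamics

`simulate_hif` offers a one-state relaxation model driven by an oxygen
schedule: constant production `beta_h` and degradation
`alpha_0 + alpha_1 · hill(O2; k_o2, m)`, mimicking oxygen-dependent
(PHD-mediated) destabilization. Defaults (`beta_h = 1, alpha_0 = 1,
alpha_1 = 10, k_o2 = 0.5, m = 2`) give a hypoxic fixed point of 1, a
normoxic fixed point near 0.1, and sub-hour relaxation, so the square
wave in oxygen produces a continuous, piecewise-smooth HIF oscillation
bracketed by the two fixed points. This is a deliberately minimal
stand-in for the full HIF stabilization cascade; every parameter is
exposed so richer forms can be substituted.

## Motif enumeration and census

A feed-forward loop rooted at a master regulator X is any ordered pair
(Y, Z) with signed edges X→Y, Y→Z and X→Z, all three genes distinct;
Y is by construction itself a regulator. Coherence follows the product
rule (coherent iff the direct sign equals the product of the indirect
signs) and types are numbered by the standard sign-triple tables. One
motif is counted per distinct (Y, Z) pair. Duplicate identically-signed
edges collapse; conflicting signs on one edge are an error by default
(curated databases can contain both modes of regulation), with a
`keep-both` policy that emits one motif per sign combination. TRRUST
dialect parsing maps Activation/Repression to ±1 and drops
`Unknown`-mode rows with a logged count.

The curated HIF-1 loop list from the reference analysis is journal
supplementary data and is not redistributed; `hiffl.datasets` instead
builds a clearly-labelled synthetic network realizing the published
census marginals (31 incoherent loops, 58.1/0.0/38.7/3.2% over types
1–4; 40 coherent loops, 77.5/0.0/22.5/0.0%) so the
enumeration-and-census machinery is exercised end to end on realistic
totals. Gene names in that network are placeholders.

## Transcriptomic pattern calling

Inputs are per-gene DE statistics (log2 fold change, BH-adjusted p) for
the three oxygen contrasts H-vs-N, O-vs-N and O-vs-H within a genotype.
A gene's N/H/O ordering is called only when all three contrasts are
significant at `alpha` (default 0.05); the three signed comparisons
then either define a unique total order or are cyclic, which is
reported as `INCONSISTENT` rather than resolved (possible because the
three contrasts are estimated independently). TF dependence: a gene is
*disrupted* when its wild-type pattern is oscillation-specific and the
knockdown genotype's call differs in any way, including loss of
significance; the knockdown genotype is not required to be
independently significant (a strict mode can demand it). The TF→gene
sign is read off the knockdown-vs-WT contrast — significant increase on
knockdown ⇒ repressor, decrease ⇒ activator — evaluated by default in
the hypoxic condition, where the HIF-activated TF is present. Putative
loops are assembled as (HIF1A, TF, gene) with the HIF→TF edge fixed
activating and the direct edge signed by the significant WT H-vs-N fold
change; coherent assemblies are returned but flagged, since only
incoherent ones can explain oscillation-specific patterns.

## Synthetic data generator

The generator emulates the reference design — genotypes WT, TP53KD,
NOTCH1KD × conditions N, H, O × 3 replicates (27 samples) — as
negative-binomial counts: gene g in sample s has mean `baseline_g ·
libfactor_s · 2^(effect + kd_shift)` with constant dispersion (default
0.1). Per-gene baselines are lognormal (median 200 counts, log-sd 1);
library factors are lognormal with CV 0.2. Replicates are independent
draws (technical-replicate correlation is not modelled). The default
planting assigns 2.5% of genes to each of the four
oscillation-specific orderings with condition effects in 2-log2 steps
(4-fold, as seen for strong hypoxia responders) and another 10% to an
ordinary dose-averaged `N<O<H` class; all oscillation-specific planted
genes are TF-dependent, assigned round-robin to TP53/NOTCH1 with
alternating regulatory sign. In the corresponding knockdown genotype
the condition effects are silenced (complete-silencing default;
`kd_efficiency` scales it) and the baseline shifts by
`−sign · kd_log2fc`. `kd_log2fc` defaults to 4: the shift must dominate
the silenced H-condition effect (±2) because the sign-inference
contrast is taken in hypoxia, where both planted signals superimpose.

What the generator does *not* emulate: mean–dispersion trends, batch
effects, gene-length/GC bias, replicate correlation, partial knockdown
compensation, or secondary (indirect) knockdown effects. Passing the
closed-loop benchmark therefore demonstrates that the pipeline's logic
recovers planted structure under idealized noise, not that real data of
this size would yield the same operating characteristics.

## Stand-in differential expression

The bundled DE step exists so the pipeline closes without an external
engine; it is not a DESeq2 reimplementation. Counts are normalized with
median-of-ratios size factors (a geometric reference over genes with no
zeros; total-count/CPM scaling is biased by composition when a large
planted fraction moves one way), rescaled to a counts-per-million unit
and log2-transformed with a 0.5 pseudo-count. The per-gene statistic is
a two-sample t on the log values with empirical-Bayes variance
moderation: per-gene pooled variances are squeezed toward a common
prior fitted by moments of log s² (scaled inverse-chi-square, prior df
from the inverse-trigamma equation), and the t statistic uses the
posterior variance with prior+residual degrees of freedom. With r = 3
an unmoderated test's variance estimate is so noisy that a material
fraction of genuinely changed genes fails any workable threshold;
moderation is the standard remedy at this design size and
`moderate=False` exposes the plain Welch test for comparison. P-values
are BH-adjusted across genes within each contrast. Reported `log2fc` is
the difference of group means of the log-transformed normalized values.

Residual caveat: with 20% of genes planted asymmetrically even
median-of-ratios normalization retains a small (~0.15 log2) global
offset; it is far below the planted 2-log2 gaps and is quantified in
the test suite.

## Problem sizes

The default benchmark runs 2000 genes × 27 samples with 11 DE contrasts
and finishes in about a second; null calibration uses 20 datasets of
1000 genes. Phase diagrams are 20×20 grids (400 joint ODE cells) per
(type, mode); the full acceptance script — census, 200 steady-state
fidelity runs, 8 RK4 cross-checks, 8 sweeps, a 3200-point steady-state
scan, the benchmark and null calibration — completes in ~10 s on one
CPU.

## Known limitations

* The generalization of the target equation to loop types 1, 2 and 4,
  and the shared `k_h` on both HIF-facing edges, are modelling choices;
  alternative parameterizations (independent direct-edge affinity,
  per-edge cooperativity) are not explored.
* The `UNRESOLVED` tie class has no counterpart in a forced-choice
  phase diagram; region fractions therefore depend mildly on
  `rel_tol`.
* Pattern calling treats the three oxygen contrasts as independent
  evidence; no joint model or ordering-aware test is fitted.
* The census input bundled here is synthetic; applying the enumeration
  to a real curated edge list requires supplying that list as a TSV.
* Only the 1 h/0.5 h cycling protocol is studied by default; other
  duty cycles are configurable but uncharacterized.
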