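# Methods

## Scope and data model

The pipeline turns three inputs — a signed causal network (the PKN), a
cue–sentinel–response perturbation dataset, and a phenotype-regulator
table — into trained Boolean logic models and downstream screens. The
canonical study system is a pair of FLT3-ITD AML cell lines (ITD in
the juxtamembrane domain = TKI-sensitive; ITD in the kinase domain =
TKI-resistant) perturbed under 16 conditions combining two cytokine
stimuli (IGF1, TNFα), six branch kinase inhibitors, and the FLT3
inhibitor, with 14 phospho-sentinels read on a bead array.

## Normalization chain

1. **Bead filter.** A well×analyte measurement is reliable only with at
   least 50 detected beads; counts strictly below 50 are excluded
   (`min_beads = 50`, configurable).
2. **Loading control.** Each analyte MFI is divided by the β-tubulin
   MFI of the same well. A well whose control is missing or
   bead-excluded has all its analytes masked.
3. **Replicates.** Median over the (three) biological replicates;
   spread is the sample SD (n−1), undefined for a single replicate.
4. **Hill rescaling.** Per analyte, `y = xⁿ/(K+xⁿ)` with `n` and `K`
   closed-form in the observed extremes so that the observed minimum
   maps to 0.001 and the maximum to 0.999. The fit pools T0 and T1
   values of the analyte: the pooled range spans the full activity
   window (inhibited minimum to stimulated maximum), which is what the
   asymptote convention assumes. Both target extremes are parameters
   (`min_t`, `max_t`).

The trainer fits the normalized T1 values; T0 is kept only for the
display quantity "activity modulation" (T1 − T0, clipped to [−1, 1]).
Whether rescaling should be per cell line or joint is left to the
caller: the pipeline operates on one dataset at a time.

## PKN preprocessing

*Compression* removes nodes that are neither measured, targeted,
constitutive, nor phenotypes: pass-through nodes are bypassed with
sign-product edges, dangling sources/sinks deleted, iterated to
fixpoint. Two guards keep this faithful and bounded: nodes with
self-loops are never bypassed, and a node is bypassed only when the
reconnection adds at most 4 edges (`MAX_BYPASS_FANPRODUCT`) — larger
hubs stay, avoiding quadratic edge blow-up where a curator would have
simplified by hand.

*Expansion* gives each node one arity-1 gate per regulator plus one AND
gate per regulator subset of size 2..`max_gate_inputs`. The default
arity cap is 2 (configurable to 4): it keeps the search space
tractable and is the conventional choice for this model class; pairs
of parallel opposite-sign edges survive as separate literals and are
disambiguated by training.

*Imputation* screens ordered pairs of measured analytes (and
cue-on/off vectors against analytes) by Pearson correlation of their
normalized T1 profiles across conditions; |r| ≥ 0.75 proposes a
data-derived edge signed by the correlation. This is a deliberately
plain stand-in for dedicated data-driven network inference: the
threshold is a config knob, provenance is tracked per edge, and
imputed edges can be ablated. Constant profiles are skipped; pairs
with an existing directed edge are not re-proposed.

## Simulation

Synchronous update: every node simultaneously becomes the OR over its
selected gates (each an AND of signed literals); nodes with no
selected gate hold their value; clamps are re-applied every step.

* **Initial state**: all non-clamped nodes 0 — the inactive/basal
  convention matching serum-starved cells before stimulation.
* **Inhibitors** clamp their target to 0 for the whole trajectory
  (node knock-down, not edge deletion). Stimuli clamp to 1. The
  constitutively active receptor set (default `{FLT3}`, reflecting
  ligand-independent ITD signaling) is clamped ON in every training
  condition unless inhibited — without this the FLT3i/no-FLT3i
  contrast would carry no information.
* **Attractors**: a repeated state with period 1 is a fixpoint; a
  longer period marks the nodes that vary within the cycle as
  UNRESOLVED while constant nodes keep their value; hitting the
  iteration cap (default 100) marks every non-clamped node UNRESOLVED.
* The engine packs one condition per bit of a Python integer, so all
  16 training conditions advance in one synchronous pass; correctness
  is checked against a naive dict-based trajectory oracle on random
  instances in the test suite.

## Fitness and training

`f = mse + θ_na·(n_unresolved/n_points) + θ_size·(selected inputs / total inputs)`

* `mse`: mean squared deviation over unmasked (condition, sentinel)
  cells; masked cells are skipped entirely.
* `θ_na = 1` per unresolved fitted cell: an unresolved prediction is
  treated as maximally wrong, discouraging models that oscillate where
  data exist.
* `θ_size = 1e−4`: a small parsimony pressure that breaks ties toward
  fewer gate inputs. It is orders of magnitude below one data cell's
  contribution, so it never trades fit for size; setting both θ to 0
  recovers pure-mse behavior.

GA defaults: population 50, 200 generations, per-bit mutation 0.01,
uniform crossover 0.7, tournament 3, elitism 2, stall limit 50. The
initial population is random at 50% density plus one all-ones
individual so the full scaffold is always evaluated. Fitness values
are cached per bitstring (populations converge, so the cache hit rate
is high). Every run records its seed; a family is `n_runs` independent
runs with consecutive seeds, keeping the `keep` best (desk scale
100/20, study scale 1000/100).

Best-model ties break by fewer selected gates, then lexicographically
smallest bitstring. The high-confidence submodel keeps gates with
family frequency strictly above 0.4.

## Phenotype inference and screens

Endpoint regulators of a phenotype are nodes annotated in the
regulator table that feed no selected gate of the high-confidence
model (terminal effectors). The phenotype level is the normalized sum
of endpoint states, activators minus inhibitors, divided by the
endpoint count — normalization makes scores comparable between models
with different endpoint counts; raw sums are recoverable by
multiplying back. "Apoptosis inhibition" is the negative of the
apoptosis level, so high values read as tumor-like. UNRESOLVED
endpoints contribute 0.5 (neutral).

Screen conditions: untreated (receptors FLT3, IGF1R, TNFR clamped ON),
FLT3i (FLT3 OFF), and FLT3i+⟨target⟩KO (both OFF). Complex targets
(ERK1/2, MEK1/2, GSK3A/B) clamp every member node. A knockout is a
rescue hit when both scores drop to the sensitive model's FLT3i levels
within ε (default ε = 0, strict; configurable because "same level" is
a judgment call on bar heights).

## Patients

ITD insertion sites classify a patient as JMD (all sites < boundary),
TKD (all ≥), or JMD+TKD. The boundary defaults to residue 610 — JMD
through 609, TKD1 from 610 — consistent with the canonical exemplars
aa 598 (JMD) and aa 613 (TKD1); it is a parameter because domain
annotations differ by a few residues between sources. JMD and JMD+TKD
patients are simulated on the JMD cell model (the JMD insertion is
dominant), TKD patients on the TKD model.

Variant annotations binarize as gain-of-function/likely GoF → clamp 1,
LoF/likely LoF → clamp 0; Unknown, Inconclusive, Likely Neutral and
Switch-of-function variants are dropped. Gene-to-node mapping goes
through an explicit alias table only — no fuzzy matching. Condition
clamps override patient clamps (a drug acts downstream of genotype),
and each override is logged. Expression z-scores (per patient: center
by the patient's mean, scale by the patient's sample SD) are computed
for description only; simulation inputs are mutational. An optional
hook to clamp by |z| threshold exists in principle but is not enabled:
the simulation recipe is mutations-only by design.

## Synthetic data

`make_truth` draws a layered signed network mirroring the study
layout: 2 stimuli → 2 ligand-gated receptors plus constitutive FLT3 →
7 downstream kinases of which 6 are inhibitable and all are measured
(12 nodes total by default). Each downstream node takes 1–2 upstream
regulators (80% activating); two-regulator nodes are, with equal
probability, a single AND gate or an OR of the two singles. Decoy
edges (about a quarter of the edge count) are drawn by rewiring
existing edges to deeper nodes, preserving out-degree and acyclicity,
so recovery is nontrivial but the truth stays identifiable. The wiring
is redrawn (deterministically from the seed) until the network
validates, ≥90% of (condition, sentinel) cells resolve, and every
sentinel profile varies across conditions — a constant readout could
never be normalized or recovered by any method.

`simulate_dataset` maps binary steady states to MFI through per-analyte
affine ranges (low 500–2000, high 8000–20000 units — a plausible
plate-reader scale; any positive affine map works because the Hill
rescaling is scale-free between observed extremes), multiplies
log-normal noise `exp(N(0, σ))` (default σ = 0.05, the replicate-level
variability the screen is expected to tolerate), emits a β-tubulin
channel with its own noise, Poisson bead counts around 120 with a 2%
fraction forced below the filter, three replicates, and T0 rows from
the unstimulated baseline state.

What this emulates: dynamic range, multiplicative noise, loading
normalization, bead dropout, replicate structure. What it does not:
antibody cross-reactivity, plate/batch effects, saturation
nonlinearity, correlated well failures, or partial target engagement
by inhibitors. Passing the recovery tests therefore shows the
estimator is correct and well-conditioned under the stated noise
model, not that real Luminex data will reach the same F1.

## Problem sizes and numerical choices

* Recovery benchmark: 12-node truth, 16 conditions, 3 replicates,
  noise SD 0.05, 100 GA runs keep-20, averaged over 5 seeds — a
  deliberate desk-scale configuration of the 1000-run study protocol
  chosen so the whole suite runs in minutes on one core.
* GA-vs-exhaustive checks use generated instances capped at 12 gates
  (≤4096 selections) so brute force is exact.
* Noise-free data sit exactly at 0.001/0.999, so a perfect binary
  model has an irreducible mse floor of 1e−6 per cell; tests assert
  against that floor, not against 0.
* Hill boundary conditions are satisfied to ~1e−15 relative; tests use
  1e−9.
* Duplicate network rows collapse on read; edge order is normalized on
  write, making SIF round-trips byte-stable.

## Known limitations

* Synchronous updates only; no asynchronous or probabilistic schemes,
  and attractor analysis stops at cycle detection from one initial
  state.
* The published scaffold sizes of the original study depend on a
  specific data-driven imputation implementation and manual curation
  loop and are not reproduced exactly; provenance tracking makes the
  imputed edge set auditable instead.
* Knockouts are binary clamps; no dose–response modeling.
* The GA offers no optimality certificate beyond the exhaustive
  cross-checks at small scale; the family/frequency machinery is the
  intended robustness layer at realistic sizes.
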