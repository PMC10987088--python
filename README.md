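# signalogic

Boolean logic modeling of intracellular signaling from perturbation
data, built around the FLT3-ITD acute myeloid leukemia (AML) use case:
a curated causal signaling network plus a cue–sentinel–response
bead-array dataset are turned into genotype-specific predictive logic
models, which are then used for in silico combinatorial drug screens
and patient-specific simulations.

## Who this is for

Systems biologists and computational oncologists who have (or can
emulate) three ingredients:

1. a **prior-knowledge network (PKN)**: a signed directed graph of
   causal regulations (SIF or SIGNOR-style TSV);
2. a **perturbation dataset**: median fluorescence intensities (MFI) of
   phospho-sentinel analytes across stimulus/inhibitor conditions, with
   bead counts and replicates;
3. a **phenotype-regulator table** linking network nodes to apoptosis
   and proliferation.

## The model

A logic model is an AND/OR hypergraph over the compressed PKN. Each
candidate *gate* is an AND of signed literals regulating one node; a
node's synchronous update is the OR over its selected gates:

```
x_i(t+1) = ∨_{g ∈ G_i} ∧_{(j,s) ∈ g} [ x_j(t) = (s+1)/2 ]
```

Clamped nodes (stimuli ON, drugged targets OFF) are re-forced every
step; the trajectory runs to a fixpoint, with nodes that oscillate in a
limit cycle reported as unresolved.

Training selects the gate subset (a bitstring) minimizing

```
f = mse + θ_na · (unresolved fraction) + θ_size · (selected input fraction)
```

where `mse` is the mean squared deviation of simulated steady states
from the normalized T1 measurements. A genetic algorithm is run many
times (study scale: 1000 runs, keep the best 100; desk scale: 100/20);
the per-gate selection frequency across the kept family is the edge
confidence, and gates with frequency > 0.4 form the high-confidence
model used for phenotype inference.

Data normalization rescales each analyte to (0, 1) with a Hill curve
`y = xⁿ/(K + xⁿ)` whose parameters are closed-form in the observed
extremes (`minS`, `maxS`, `b = maxS/minS`):

```
n = log( (1−minT)·maxT / ((1−maxT)·minT) ) / log b ,   K = (1−maxT)/maxT · maxSⁿ
```

so that `y(minS) = minT = 0.001` and `y(maxS) = maxT = 0.999`. Upstream
of this sit the 50-bead reliability filter, division by the β-tubulin
loading control, and the median/SD over the three biological
replicates.

## Worked example

The packaged demo pair of models are synthetic stand-ins for the
TKI-sensitive (ITD in the juxtamembrane domain, JMD) and TKI-resistant
(ITD in the kinase domain, TKD) genotypes; the resistant model carries
a TNFR→JNK→STAT5 bypass that keeps the survival axis on under FLT3
inhibition.

```python
from signalogic.synthetic import demo_model_pair
from signalogic.phenotype_screen import endpoint_regulators, ko_screen, rescue_hits

sensitive, resistant, regtable = demo_model_pair()
eps_r = endpoint_regulators(resistant, regtable)
screen = ko_screen(resistant, eps_r)
for row in screen.rows:
    print(row.condition, row.scores.proliferation_activation,
          row.scores.apoptosis_inhibition)

eps_s = endpoint_regulators(sensitive, regtable)
reference = ko_screen(sensitive, eps_s, targets=()).scores_for("FLT3i")
print("rescue hits:", rescue_hits(screen, reference))
```

prints

```
untreated 1.0 0.5
FLT3i 1.0 0.5
FLT3i+IGF1RKO 1.0 0.5
FLT3i+JNKKO 0.0 -0.5
rescue hits: ['JNK']
```

Read: the resistant model stays fully proliferative (score +1) with
apoptosis suppressed (+0.5) under FLT3 inhibition alone; only the
combined FLT3i + JNK knockout drops both scores to the sensitive
model's treated levels (0, −0.5), so JNK is called as the rescue
co-target.

The same pipeline runs end to end from the shell on synthetic data:

```sh
signalogic synth --seed 7 --out run
signalogic normalize  --raw run/raw.csv --design run/design.yaml --out run/midas.csv
signalogic preprocess --network run/pkn.sif --design run/design.yaml \
                      --midas run/midas.csv --out run/scaffold.json
signalogic train --scaffold run/scaffold.json --midas run/midas.csv \
                 --design run/design.yaml --runs 100 --keep 20 --out run/train
```

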