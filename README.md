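# gentox

Integrated *in vitro* genotoxicity assessment in Python: a tested, reusable
implementation of a modern NAM-based (new-approach-methodology) screening
pipeline for data-poor chemicals.

## Who this is for

Genetic toxicologists and computational toxicologists who want the analysis
half of an integrated screen — the statistics between well-level /
count-level assay exports and a per-compound hazard call and potency rank —
as a library and CLI, with a synthetic-study generator so every stage can be
exercised and validated without instrument data.

## What it implements

The pipeline integrates three assays run on TK6 cells over geometric
("half-log", 70.71 % spacing) concentration series, then models potency and
ranks compounds:

1. **Transcriptomic DDI classification** (`gentox.tgxddi`) — a biomarker gene
   panel is compared against a labeled reference set of chemicals with known
   DNA damage-inducing (DDI) / non-DDI mechanisms by a three-pronged
   ensemble: nearest shrunken centroids with posterior probabilities (call
   only when the posterior exceeds 0.90), projection on the training set's
   first principal component (negative PC1 ⇒ DDI), and joint hierarchical
   clustering (Euclidean, average linkage) cut at the top split.  A compound
   is DDI if any method at any concentration says so.
2. **Micronucleus (MN) calling** (`gentox.microflow`) — %MN = 100·MN/nucleated
   events; wells gated at relative survival < 40 % or fold-EMA > 4; a
   positive call needs a ≥ 2.50-fold %MN increase together with a
   Holm-Šidák-adjusted Poisson-regression p < 0.05 at a non-gated
   concentration.
3. **Mode-of-action calling** (`gentox.multiflow`) — γH2AX and p53
   fluorescence shifts, %p-H3 and %polyploidy, expressed as fold-changes over
   solvent control and compared against Global Evaluation Factors
   (e.g. 4H γH2AX 1.51, 24H γH2AX 2.11, 24H polyploidy 5.86).  Two set
   biomarkers over threshold at two successive non-cytotoxic concentrations
   give a robust clastogen/aneugen call; both sets ⇒ pan-genotoxic.
4. **Benchmark concentrations** (`gentox.bmc`) — gene-level BMCs from an
   AIC-selected family (Exp2–5, Linear, Poly2, restricted Power) at a
   1-SD benchmark response, prefiltered by a permutation Williams trend test
   and a 1.5-fold floor, screened by confidence-ratio filters
   (BMC/BMCL ≥ 20 etc.), and summarised as a bootstrap median gene-set BMC;
   flow endpoints fitted with the 5-parameter exponential
   y = a[c − (c−1)e^−(x/b)^d] at a relative benchmark (CES 1.0 for MN,
   0.5 for the DNA-damage biomarkers).
5. **ToxPi integration** (`gentox.toxpi`) — per-endpoint BMC confidence
   limits are −log10-transformed, summed, baseline-anchored (10,000 µM
   substitution for inactive endpoints), normalized per slice, and combined
   with weights 1/3 (TGx-DDI) + 1/3 (MN) + 4 × 1/12 (the four γH2AX/p53
   timepoints) into an overall score, rank, and profile clustering.
6. **Integrated hazard call** (`gentox.pipeline`) — the three per-assay calls
   map to a category: genotoxic (clastogen / aneugen / pan), likely
   irrelevant MN positive, possibly genotoxic with ambiguous MoA, or
   non-genotoxic.

The synthetic generator (`gentox.simulate`) produces study-shaped inputs —
a 28-chemical training set, 6-point duplicate expression series, 10-point
flow plates with solvent controls — whose class labels, MoA labels and true
BMCs are known analytically.

## Worked example

```python
from gentox.simulate import SimulationConfig, simulate_expression_study, simulate_flow_study
from gentox.tgxddi import TgxDdiClassifier
from gentox.microflow import call_mn
from gentox.multiflow import compute_multiflow_endpoints, fold_table_from_endpoints, call_moa
from gentox.pipeline import integrated_call, collapse_s9

cfg = SimulationConfig(seed=1)          # 4 demo compounds, known truth
training, samples, truth = simulate_expression_study(cfg)
micro, multi = simulate_flow_study(cfg, truth)

tgx = TgxDdiClassifier(training).overall_calls(samples)
mn = call_mn(micro)
ep = compute_multiflow_endpoints(multi)
for name in truth.class_label:
    moa = call_moa(fold_table_from_endpoints(ep, name))
    call = integrated_call(name, collapse_s9(tgx[name] == "DDI"),
                           collapse_s9(mn[name].positive), moa)
    print(f"{name:9s} tgx={call.tgx} mn={call.mn} moa={moa.call:13s} -> {call.category}")
```

prints

```
CLAST-1   tgx=+ mn=+ moa=clastogen     -> genotoxic-clastogen
ANEU-1    tgx=- mn=+ moa=aneugen       -> possibly-genotoxic-ambiguous
PAN-1     tgx=+ mn=+ moa=pan-genotoxic -> genotoxic-pan
NEG-1     tgx=- mn=- moa=non-genotoxic -> non-genotoxic
```

`CLAST-1` is a simulated clastogen: positive in all three assays, so the
integrated category is genotoxic with a clastogenic MoA.  `ANEU-1` is an
aneugen built to be transcriptomically silent (the DDI biomarker responds
weakly to aneugens): MN-positive and aneugenic by the biomarker assay but
non-DDI, an off-table combination the rule maps to
possibly-genotoxic-ambiguous with a logged note.  `NEG-1` is inactive
everywhere.

The same study runs end to end from the shell, writing per-assay endpoint
tables, the BMC table, ToxPi scores, integrated calls and a run log:

```bash
gentox run-all --seed 1 --outdir results/demo
```

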