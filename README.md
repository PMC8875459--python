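# npflux

Prioritising natural products as anticancer drug candidates from
constraint-based metabolic models.

Natural products act on many targets at once and their target annotations
are chronically incomplete, so classical single-target knockout screens miss
candidates. `npflux` implements a four-step workflow that instead compares
**context-specific metabolic models** — sub-models of a genome-scale
reconstruction built from the expression profiles of treated cells — against
a control (vehicle) model:

1. **Target-deletion growth prediction.** For each compound with known
   targets, the target genes are knocked out in the control model via the
   boolean gene–protein–reaction (GPR) rules and the growth ratio
   `grRatio = v_KO / v_WT` of the biomass flux is computed by flux balance
   analysis (FBA). `grRatio = 0` predicts growth arrest. Combination
   knockouts and per-gene deletions refine the call.
2. **Reaction-content dissimilarity.** Each treated context model is
   compared to the control by the Jaccard dissimilarity of their reaction
   sets, `D = 1 − |A∩B| / |A∪B|`; the top-k most dissimilar products are
   retained.
3. **Flux-range similarity to reference drugs.** Flux variability analysis
   (FVA) gives per-reaction flux ranges `[vmin, vmax]`. Two models are
   compared by the mean regularised range overlap

       si = mean_r  max(0, min(v1max, v2max) − max(v1min, v2min) + ε)
                    ─────────────────────────────────────────────────
                        max(v1max, v2max) − min(v1min, v2min) + ε

   over the union of their reactions (a reaction absent from one model
   contributes `[0, 0]`; ε = 1e-4). Approved drugs whose knockout model has
   flux dissimilarity `1 − si > 1e-4` to control serve as references, and
   products in the combined top-k similarity to any reference are retained.
4. **Pathway alteration.** Per pathway (subsystem), the presence rate is the
   fraction of the reference reconstruction's reactions retained in a
   context model. Products with a known target in the pathway of interest
   and a nonzero treatment-minus-control presence-rate difference there are
   retained. Pathways with ≤ 3 reactions are excluded and the report is
   ranked by the interquartile range of differences across products.

Products flagged by ≥ 2 steps are selected (curated include/exclude lists
handle toxicity and external evidence), yielding the final candidate table.

Context models are built with a flux-consistency pass (every retained
reaction must support |flux| ≥ ε at steady state) followed by a core-
expansion extraction: expression scores are thresholded into active /
inactive / unknown genes, GPR rules map active genes to core reactions, the
biomass reaction is always forced into the core, and the growth medium
closes all uptake exchanges for absent nutrients.

## Worked example

`examples/05_full_workflow.py` generates a synthetic treated-vs-control
study (6 pathways × 6 reactions, 8 product conditions, 4 reference drugs)
with two planted signals — `NP_01` targets the transporter the biomass
pathway depends on, and `NP_02`'s expression shuts down `PATHWAY_3` — and
runs the whole workflow:

```
reference cancer drugs (flux dissimilarity to control above 1e-4): ['CD_01', 'CD_02', 'CD_03']

         step1_deletion  step2_dissimilarity  ...  n_steps   verdict
product
NP_01                 1                    1  ...        3  selected
NP_02                 0                    1  ...        2  selected
NP_03                 0                    1  ...        2  selected
NP_04                 0                    0  ...        1  rejected
NP_05                 0                    0  ...        1  rejected

validated candidates: ['NP_01', 'NP_02', 'NP_03']
planted truth: ['NP_01'] + shutdown of {'NP_02': 'PATHWAY_3'}
```

`NP_01` is flagged by the deletion step (`grRatio = 0`) and `NP_02` by the
content and pathway steps; both planted signals are recovered. The other
examples (`examples/01`–`04`) walk through FBA/knockouts, context-model
extraction, the two dissimilarity scores and the pathway report
individually, each printing the numbers it computes.

The same functionality is available from the shell:

```
npflux simulate --seed 0 --out-dir scenario/
npflux run --config scenario/run.yml --out-dir results/
npflux build | deletion | score-content | score-flux | pathways --help
```

Every command writes TSV outputs plus a `manifest.json` with input digests
and timings; reruns with identical inputs are byte-identical.

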