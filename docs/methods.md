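# Methods

## Model representation

A `MetabolicModel` is an ordered list of reactions over declared
metabolites, each reaction carrying flux bounds in mmol/gDW/h, a sparse
stoichiometry, an optional subsystem (pathway) label and an optional GPR
rule — a boolean AND/OR tree over gene identifiers (AND = enzyme complex,
OR = isozymes). One reaction, the biomass pseudo-reaction, is the FBA
objective. Invariants (unique ids, `lb ≤ ub`, declared metabolites only,
existing objective) are enforced at construction.

Exchange reactions are detected structurally: exactly one nonzero
stoichiometric entry. Uptake is the direction that brings the metabolite
into the system — negative flux for the conventional `m_e → ∅` formulation
with coefficient −1, positive flux when the coefficient is +1. Medium
constraining closes the uptake direction of every exchange whose metabolite
is not in the medium list; it never widens a bound and is idempotent.

Models are serialised as SBML Level 3 Version 1 with the FBC v2 package
(flux-bound parameters, objective, gene-product associations) plus
FBC-groups for subsystem labels; a `SUBSYSTEM:` key in reaction notes is
accepted on read as a fallback. Gene identifiers with transcript suffixes
(`.1`, `.2`, …) are stripped on load, since transcripts cannot be matched
unambiguously to expression data. An internal JSON dialect mirrors the
in-memory structure one-to-one. Read∘write is the identity up to
unrepresentable details (GPR trees re-associate n-ary AND/OR, which
preserves semantics).

## Linear programming

All analyses share the steady-state polytope `S·v = 0, lb ≤ v ≤ ub` and are
solved with HiGHS through `scipy.optimize.linprog` at feasibility/optimality
tolerance 1e-9. FBA maximises the biomass flux; unboundedness is reported as
a status rather than raised, since it indicates a modelling artefact, not a
numerical failure. FVA solves two LPs per reaction under the extra
constraint `v_obj ≥ f · v_obj*`; the optimum fraction `f` defaults to 1.0
(the classical toolbox default) and is exposed in the configuration because
published workflows rarely state it — results at `f = 1.0` describe
behaviour at maximal growth only.

Gene knockouts follow GPR semantics: knocked genes are set false, the tree
is evaluated, and every reaction whose rule evaluates false gets bounds
(0, 0); reactions without gene control are never disabled. `grRatio` is the
knockout optimum over the wild-type optimum. Ratios below 1e-6 are reported
as exactly 0: observed knockout outcomes cluster tightly at 0 or 1, and a
hard zero makes the growth-arrest classification reproducible. A
non-growing wild type raises an explicit error, since ratios would be
undefined. Combination deletions flag synergy when the combined ratio drops
more than `synergy_delta` (default 0.01) below the better single knockout —
the margin is configurable because "significant reduction" has no canonical
threshold.

## Flux consistency and context extraction

A reaction is *blocked* if it cannot carry `|v| ≥ ε` in any steady state
within bounds, with `ε = 1e-4` by default (the same magnitude as the score
regularisation; well above solver tolerance, well below typical fluxes).
The consistency check implements the classical block-LP scheme: one LP
(maximise Σ min(v_i, ε) over candidates) certifies many irreversible
reactions per solve; reversible survivors are retried with flipped
direction, then one by one, before being declared blocked. Direction
flipping happens only inside the check's working copies — returned models
keep their declared reversibilities.

Context extraction expands a *core* of required reactions into a
flux-consistent sub-model by the iterative two-LP scheme of the
FASTCORE-family algorithms: the first LP pushes unsatisfied core reactions
to ε, the second minimises the weighted L1 norm of non-core flux while
holding the satisfied core at ε; the union of the resulting supports is the
output. The output provably contains the core and every retained reaction
carries |flux| ≥ ε within the sub-model (each support is itself a feasible
mode of the sub-model). Minimality is *not* guaranteed — the heuristic
trades it for determinism; ties are broken in declaration order. A core
reaction that cannot reach ε raises an error naming the reactions.

Expression enters through two thresholds rather than a microarray
normalisation pipeline: scores ≥ high (default 1.0) call a gene active,
≤ low (default 0.0) inactive, in between unknown. A reaction is core when
its GPR is satisfied by active genes alone; a reaction that fails that test
but would pass if unknown genes were active is *unpenalised* (weight 0 in
the L1 objective) — neither forced in nor pushed out — as are reactions
without gene control. The biomass reaction is always added to the core. The
per-condition pipeline applies the medium once, reduces to the consistent
sub-network, and extracts per condition.

## Scores

*Content*: `D = 1 − |A∩B|/|A∪B|` over reaction-id sets; 0 iff identical,
1 iff disjoint, symmetric. Both-empty input is an error rather than a
convention.

*Flux*: per-reaction regularised range overlap (README formula), averaged
over the **union** of the two FVA tables with absent reactions as `[0, 0]`.
The union (rather than a fixed global universe) is used because the
comparison is defined by what either model can do; the alternative is a
configuration away in the CLI design but not a default. ε (default 1e-4)
makes two zero-width identical ranges — including two absences — score 1,
and keeps the score in [0, 1]. Terms are computed in double precision, no
rounding before the mean; outputs print to 6 decimals.

Rankings are stable sorts, descending on the score with alphabetical
tie-breaks, so top-k lists are deterministic.

## Pathway analysis

Pathways are the subsystem labels of the reference model; unlabeled
reactions group under `UNASSIGNED`. A reaction belongs to exactly one
subsystem. "Active in a context model" means *present* (set membership),
not flux-carrying: presence is what extraction decides, and flux-carrying
would conflate the measure with the FVA step. Presence rate = retained
reactions / reference reactions per pathway. The alteration report drops
pathways with ≤ 3 reactions (default) because a single reaction flip there
dominates the rate, ranks pathways by the interquartile range of
treatment-minus-control differences (linear-interpolation quantiles; the
choice of quantile method is immaterial at these sizes but fixed for
determinism), and flags rows with |difference| ≥ 0.1 (default) for display.

Drug-to-pathway target counting: a drug counts for a pathway iff at least
one of its target genes controls at least one reaction there; per-pathway
gene-controlled reaction counts are included for normalisation. Drug class
(natural product vs approved drug) is an explicit column in the target
table, never inferred from names.

## Selection

Step flags: (1) `grRatio = 0` on the control model; (2) membership in the
top-k content dissimilarity (default k = 5); (3) membership in the union of
top-k flux-similarity lists across reference drugs (default k = 10),
reference drugs being those with flux dissimilarity to control above 1e-4;
(4) a known target gene in the pathway of interest *and* a nonzero
presence-rate difference there (the "nonzero" floor is configurable;
any nonzero difference counts by default). Verdicts: `selected` iff
≥ `min_steps` (default 2) flags and not excluded; `excluded` with the
recorded reason overrides everything; `included_by_evidence` for products
kept on external evidence regardless of flag count; `rejected` otherwise.
Curation — toxicity, prior literature, database evidence — is modelled
purely as these explicit lists; nothing is inferred or mined. The
aggregation is order-independent and the verdict partition exhaustive.

The packaged `data/table2.tsv` carries the published worked example's
23 products × 4 step flags; applying the rule with its curation lists
yields 9 validated products, which the acceptance suite checks.

## Synthetic data

The generator emulates a treated-vs-control expression study: one control
condition, one condition per product, a target table covering natural
products and reference drugs, and a medium listing every importable
nutrient. The network has `n_pathways` (default 6) labelled pathways of
`reactions_per_pathway` (default 6) reactions: a gene-controlled
transporter plus parallel conversions, pathway 1 feeding biomass, the
others ending in demand exchanges. Parallel conversions (rather than a
single chain) keep noise local: losing one conversion changes one
reaction's presence, not the whole pathway's. GPRs mix single genes, OR
isozyme pairs and one AND complex per pathway.

Expression scores are drawn from N(2, 0.5²) for active genes and
N(−2, 0.5²) for inactive ones, clipped just beyond the default thresholds
(≥ 1.1 / ≤ −0.1) so that intended calls are unambiguous at noise 0; the
noise rate is the probability of flipping a gene's intended label in a
product condition (the control is noise-free). Planted essential products
target the single-gene transporter of the biomass pathway; planted
shutdowns score a whole pathway's genes low and receive one target gene
there. One seeded generator drives all randomness.

Default scenario sizes (6×6 network, 12 products, 4 reference drugs,
recovery over 100 seeds) keep the full acceptance run in tens of seconds on
one CPU while leaving every pathway above the size-exclusion threshold and
every step with a nonempty candidate pool.

What the synthetic scenarios do **not** emulate: microarray probe
structure, normalisation artefacts, correlated gene modules, genome-scale
network size (thousands of reactions), or incomplete/wrong target
annotations beyond simple absence. Passing the planted-recovery checks
shows the machinery is correct and the signals identifiable under the
stated noise model — not that the workflow's biological predictions on real
data are validated.

## Known limitations

- Extraction minimality is heuristic; different but equally valid
  sub-models exist, and declaration order decides among them.
- FVA is plain (no loopless correction), so thermodynamically infeasible
  cycles can widen ranges.
- The FVA optimum fraction used in the scoring step materially affects the
  flux similarity score; the default (1.0) describes maximal-growth states
  only.
- Name-space matching between medium lists and model metabolites is the
  caller's responsibility; no identifier mapping is attempted.
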