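"""Model-content and flux-range dissimilarity scores.

Compares context models against the control two ways: the Jaccard
dissimilarity of their reaction sets (structure) and one minus the mean
FVA flux-range overlap (behaviour).  Identical models score 0 on both.
"""

import npflux as nf

scenario = nf.make_scenario(nf.ScenarioSpec(seed=0))
models = nf.build_context_models(
    scenario.model, scenario.expression, scenario.medium, 1.0, 0.0
)
control = models["DMSO"]
product, _ = scenario.spec.planted_pathway_shutdown[0]

content = nf.jaccard_dissimilarity(
    models[product].reaction_ids, control.reaction_ids, product
)
print(f"content dissimilarity D = 1 - J of {product} vs control: "
      f"{content.dissimilarity:.3f} (J = {content.jaccard:.3f})")

fva_control = nf.flux_variability(control, fraction_of_optimum=1.0)
fva_product = nf.flux_variability(models[product], fraction_of_optimum=1.0)
flux = nf.flux_dissimilarity(fva_product, fva_control, epsilon=1e-4)
print(f"flux-range dissimilarity 1 - si of {product} vs control: "
      f"{flux.dissimilarity:.4f} (mean overlap si = {flux.si:.4f})")

# a model compared with itself scores 0 on both measures
self_score = nf.flux_dissimilarity(fva_control, fva_control, 1e-4)
print(f"control vs itself: {self_score.dissimilarity:.4f}")
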