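"""Encode an enzymatic reaction as activity-flow triad edges.

Shows the conversion rule on a glycolytic step: substrate and enzyme each
activate the product, the enzyme inhibits (consumes) the substrate, and
currency metabolites are excluded before expansion.
"""

from causalmet import MetabolicReaction, reaction_to_af_edges

reaction = MetabolicReaction(
    reaction_id="HK", pathway="Glycolysis",
    substrates=("glucose", "ATP"), products=("glucose-6P", "ADP"),
    enzymes=("HK1",))

for edge in reaction_to_af_edges(reaction):
    arrow = "->" if edge.sign > 0 else "-|"
    print(f"{edge.source:10s} {arrow} {edge.target:12s} "
          f"(s={edge.score}, {edge.mechanism})")

print()
print("ATP and ADP are currency metabolites, so only the glucose/HK1 triad")
print("remains: 3 edges, enzyme->substrate negative, everything else")
print("positive, all at the small-molecule default score 0.8.")
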