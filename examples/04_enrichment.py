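"""Compare a gene class against randomized gene lists.

Scores the mini study, then asks whether the class of planted-close genes
is significantly closer to metabolic pathways than random lists of the
same universe, using the two-sided t comparison against the null spread.
"""

from causalmet import enrichment_report, mini_study, score_network

study = mini_study(seed=42)
scoring = score_network(study.network, study.pathway_defs)

classes = {"QACT": "planted", "QINH": "planted"}
report = enrichment_report(scoring, classes, k=10, reps=300, seed=5)
close = report[report.direction == "CLOSE"]
print(close.to_string(index=False))
print()
print("Both planted genes are significantly close (observed fraction 1.0),")
print("while random 10-gene lists average the null_mean fraction; the")
print("stars encode the two-sided p bands (* <0.025 ... **** <0.000025).")
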