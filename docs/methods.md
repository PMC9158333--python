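# Methods

## Model

The interactome is a signed directed multigraph. Nodes are biological
entities (proteins, complexes, protein families, small molecules,
chemicals, phenotypes, stimuli, fusion proteins, miRNAs, antibodies);
edges are causal links with a sign (+1 activating, −1 inhibiting, 0 when
the effect verb carries no usable direction, e.g. complex formation) and
a reliability score *s* ∈ [0.1, 1]. The functional distance of an edge is
d = 1 − s ∈ [0, 0.9]. Network assembly keeps only direct interactions by
default, restricts to human records while retaining taxon-free entities
(phenotypes, chemicals), maps effect verbs to signs by prefix
("up-regulates…" → +1, "down-regulates…" → −1, everything else → 0),
drops self-loops, and collapses parallel records with identical
(source, target, sign) onto the maximum score with the union of
provenance — the path statistic of interest is a minimum distance, so the
best-supported version of a link is the relevant one. Score-less records
receive 0.8 when either endpoint is a chemical or small molecule and 0.5
otherwise (with a warning); out-of-range scores are clamped to [0.1, 1]
with a warning rather than rejected.

Metabolic reactions enter the same graph through the activity-flow triad:
substrate→product (+), enzyme→product (+), enzyme→substrate (−).
Multi-substrate/product reactions expand by full cross product, giving
|S|·|P| + |E|·|P| + |E|·|S| edges; enzyme-free reactions emit only the
substrate→product edges (spontaneous conversion). Reversible reactions are
stored as two directional reactions, expanded at load time, because
activity-flow edges are directional. A configurable currency-metabolite
list (ATP, ADP, AMP, GTP, GDP, NAD(H), NADP(H), FAD(H2), H2O, Pi, PPi,
CO2, H+, CoA by default) is excluded before expansion; without it, shared
cofactors create two-step shortcuts between biochemically unrelated
pathways. Generated metabolic edges carry the small-molecule default
score 0.8 (distance 0.2), configurable per conversion.

Pathways are named enzyme sets with a flagged rate-limiting subset (RLE);
an optional demerge mapping replaces one curated pathway by sub-pathways
(e.g. splitting glycolysis from gluconeogenesis), which is how nine
curated pathways become ten analysis pathways.

## Path search and proximity call

For a query gene and a pathway, the search enumerates **all simple
directed paths with at most 4 edges** (cutoff configurable) from the gene
to the pathway's RLE set, traversing only signed edges. Unsigned edges
are excluded by default; if admitted (`include_unsigned`), any path
containing one is classed *indeterminate* and excluded from up/down
fractions, since the parity rule is defined only for inhibitory vs
non-inhibitory steps. Antiparallel +1/−1 edges between the same node pair
are distinct traversable edges (multigraph keyed by sign), so they yield
distinct paths. A target RLE terminates a path — no enumerated path
crosses an RLE of the *target* pathway as an intermediate — while RLEs of
other pathways and non-RLE members of the target pathway are traversed
freely. Enumeration is implemented over `networkx.all_simple_edge_paths`
with a termination post-filter, and returns paths in lexicographic order
by node sequence for determinism; the test suite checks it against an
independent recursive depth-first oracle on hundreds of random networks.

Path distance = Σ (1 − s) over edges; path sign = parity of the count of
−1 edges (equivalently the sign of the product of edge signs). The
gene-level distance is the minimum over paths (mean aggregation available
as an option). A gene that *is* an RLE of the pathway contributes the
zero-length self-path: distance 0, one activating path that is excluded
from up/down path counts.

Genes with no path within the cutoff are imputed the **highest finite
gene-level distance** in that pathway's distribution (imputed values are
excluded when computing the maximum, avoiding circularity). Z-scores are
computed over the full distribution — every universe gene, imputed values
included; the universe is the set of protein-class entities. The
population standard deviation (ddof = 0) is used by default and is
switchable; with ≥ ~8000 genes the sample/population difference is far
below the call threshold. Significance is the strict inequality
Z < −1.96, the two-sided normal p < 0.05 boundary; the reported p is the
two-sided normal tail of Z. Degenerate distributions (< 2 genes, zero
spread, or no gene reaching any RLE) raise an explicit error rather than
returning silent zeros.

A gene's verdict (activator / inhibitor / mixed) is the majority sign
among its signed paths to the pathway, ties → mixed.

## Randomization test

The observed statistic of a gene class — the fraction of its genes
significantly close to ≥ 1 pathway, or the pooled fraction of
activating (UP) / inhibiting (DOWN) paths its significant genes send into
one pathway — is compared against the same statistic on random lists
sampled without replacement from the protein universe, by default 1000
lists of 700 genes (the size of the curated cancer-gene catalogue the
method was designed around). Replicates where a fraction is undefined
(no signed path from the sampled list) are recorded as NaN and excluded,
never counted as zero.

The comparison is a two-sided one-sample t of the observed value against
the null distribution: t = (obs − μ₀) / (σ₀ · √(1 + 1/n)) with n − 1
degrees of freedom, where μ₀ and σ₀ are the mean and (sample) sd of the
valid replicates. Scaling by the null spread, not by the standard error
of the null mean, is what makes the test calibrated: an observation drawn
from the null itself is starred at the * level in ≈ 2.5% of studies
(verified in the test suite at 500 simulated studies). The naive
standard-error variant (`method="mean"`, scipy's one-sample t-test) is
provided for comparison but is anticonservative by a factor of √(n+1) in
this design. Stars encode two-sided p bands with strict inequalities:
* < 0.025, ** < 0.0025, *** < 0.00025, **** < 0.000025. No
multiple-testing correction is applied across pathways; the per-pathway
stars are reported as-is, mirroring the figure convention of the analyses
this tool supports.

Randomness: a single integer seed; the replicate streams are split by
`numpy.random.SeedSequence.spawn`, so results are bit-reproducible and
independent of evaluation order. The sampling universe is sorted before
indexing so the distribution does not depend on input order.

## Synthetic data

The generator emulates the study conditions end to end: a uniform random
simple directed graph (distinct ordered pairs, no self-loops) with
inhibiting probability 0.25–0.3 and scores uniform on the score range
[0.1, 1]; per pathway, a linear chain of single-substrate reactions
(connected metabolite graph) with the first `rle_per_pathway` enzymes
flagged as rate-limiting; optional sharing of terminal metabolites so all
pathways merge into one connected metabolic component; random
signalling→enzyme "crosstalk" edges that give background genes a baseline
chance of reaching RLEs; and `plant_path`, which inserts a guaranteed
simple path with chosen signs and scores through fresh intermediate
nodes and records its analytic distance and parity sign as ground truth.
Scores are rounded to 6 decimals at generation so that fixture files
round-trip exactly through the TSV readers. Fixtures are emitted in the
same dialects the real readers consume (causal-interaction TSV, reaction
TSV, pathway YAML, gene-class CSV) — one code path for synthetic and real
data.

The shipped `mini_study` (60 genes, 150 edges, 2 pathways, seed 42)
plants a significant activator (QACT, distance 0.15), a significant
inhibitor (QINH, 0.20), three background genes with long weak routes that
anchor the imputation value, and a length-5 negative control (QFAR) that
the bounded search must not find.

What the generator does **not** emulate: the degree distribution, motif
content and curation biases of a real literature-curated interactome,
correlated annotation between classes, or per-reaction score variation.
Passing tests therefore demonstrate the correctness of the machinery —
enumeration, scoring, imputation, parity, calibration — not the
biological effect sizes a real curated network would produce.

## Problem sizes and the acceptance study

`scripts/acceptance.py` regenerates a full study at a chosen seed:
1200 genes, 2400 signalling edges (mean out-degree 2), four pathways of
six enzymes (two rate-limiting each) embedded through the triad rule,
80 crosstalk edges, a 245-gene cancer-like class of which 30% receive a
planted 1–3-step route (scores 0.7–0.95) to a random RLE, and the full
1000×700 randomization test. The wiring density was chosen so that the
network operates in the published regime of the method — the clear
majority of genes cannot reach a rate-limiting enzyme within four steps,
and roughly a fifth of random genes are called significantly close; in a
much denser network the distance distribution compresses and Z < −1.96
becomes unattainable for any gene (the call requires μ/σ > 1.96), which
is a genuine property of the statistic worth knowing when applying it to
other networks. At these sizes the script completes in a few seconds.

## Known limitations

- Bounded enumeration is exponential in the cutoff; cutoff 4 on a
  curated-interactome scale is fine, but dense graphs at higher cutoffs
  grow quickly.
- The proximity call ignores whether a path's genes are expressed in any
  particular cell context; paths are hypotheses for expert triage.
- The imputation rule puts all unreachable genes at a single point mass,
  which makes the Z-distribution strongly bimodal; the −1.96 threshold
  should be read as a ranking device, not a calibrated error rate across
  genes.
- Parallel paths through entity-class variants (protein vs family nodes)
  are counted separately in up/down fractions.
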