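# Methods

This note documents the models and procedures implemented in `secircuit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Super-enhancer calling

Stitching merges peaks transitively whenever the gap between consecutive
peaks (`next.start − current_hull.end`) is at most the stitching distance
(default 12,500 bp). Peaks overlapping any TSS ± 2,500 bp window (both
window ends inclusive) are excluded from stitching but kept as standalone
single-constituent regions — exclusion removes them from merging, not from
existence. Coordinates are 0-based half-open throughout.

Region score is the constituent sum of (sample − input) signal, clamped at
zero on the sum: negative aggregate enhancer signal is treated as noise.
Ranking is a stable descending sort with ties broken by (chrom, start).

The SE cutoff is the discrete slope-1 tangent of the 0–1-scaled ascending
rank curve: cutoff index = argmin (yᵢ − xᵢ), ties resolved to the largest
index so that tie cases yield the fewest super-enhancers (a linear curve
therefore yields none). Degenerate inputs — fewer than three regions or
constant scores — return zero super-enhancers with a degenerate flag
rather than an arbitrary cut. For the convex family s = x^k this discrete
rule converges to the analytic tangent x* = (1/k)^(1/(k−1)), which the
test suite checks at k = 2, 3, 5.

Gene assignment minimises |TSS − region midpoint| (midpoint =
⌊(start+end)/2⌋), ties to the smaller TSS then lexicographic gene id;
regions on chromosomes without annotation stay unassigned. Nearest-TSS
from the midpoint was chosen over nearest-gene-body because it is
deterministic and directly checkable against an exhaustive oracle;
tools that annotate "adjacent genes" may differ near equidistant pairs.

## Differential integration

The two conditions' SE gene sets decompose into lost / gained / shared;
the module guarantees |lost| + |shared| = |model set| and |gained| +
|shared| = |treated set| on any input. DEG filtering uses one adjusted-p
cutoff (default 0.05) — the dual Q/FDR phrasing of common DESeq2
workflows names the same quantity — and direction by strict sign of
log2FC with no magnitude cutoff by default (`lfc_min = 0`, exposed). With
a model-vs-treatment fold-change convention, "up after treatment" is the
DEG table's down set; `intersect_candidates` encodes both rules
(`lost_up_model`, `gained_up_ea`) and records provenance. An empty
intersection is a reported result, not an error.

## Key-gene prioritisation

The random forest is a bagging ensemble of CART trees (scikit-learn base
learner, `max_features = √p`, unlimited depth), grown one tree at a time
from a single seeded RNG so the out-of-bag (OOB) error is available for
every forest size 1…max_trees (default 500). The OOB error at size t is
the misclassification rate of the majority OOB vote over the first t
trees, over samples with at least one OOB vote. The chosen forest size is
the smallest minimiser — the cheapest adequate forest, deterministically.
Importance is the unnormalised mean decrease in Gini impurity averaged
over trees (the classical MDG), ties broken lexicographically; constant
features keep MDG 0 rather than being dropped.

Semantic similarity uses the Wang graph method: S-values propagate from a
term through its ancestors with edge weights 0.8 (is_a) and 0.6 (part_of)
— the conventional defaults of the measure — and gene–gene similarity is
the best-match average over term sets. Gene score is the mean similarity
to the other candidates (self excluded); unannotated genes are excluded
with a warning. No external similarity implementation is available in
this environment, so correctness rests on hand-computed small cases and
an exhaustive pairwise recomputation in the tests.

The core gene is the intersection of the two top-k lists (k = 3 default);
it may be empty or contain several genes, both reported as-is.

## CRC inference

Active genes are operationalised as genes assigned to a called SE. Motif
scanning discretises log2-odds scores to integer units of 1/1000; the
score distribution of a random background k-mer is computed exactly by
position-wise convolution, and the scan threshold is the smallest
discretised score whose tail probability is ≤ the p-value threshold
(default 10⁻⁴). Both strands are scanned at every offset of every SE
constituent; `N` bases contribute zero log-odds (the background
expectation). The scanner and the threshold share the same integer
matrix, so the cut is exact by construction; the tests verify the DP
against full 4^k enumeration and the realised per-position hit rate
against its Monte-Carlo expectation.

Self-regulation requires ≥ 3 own-motif hits pooled across a TF's SE
constituents; the same instance rule defines edges A→B into other
self-regulating TFs' SEs (a TF with several SEs pools hits across all of
them). Circuits are maximal sets (size ≥ 2) in which every ordered pair
has an edge — maximal cliques of the bidirectional-edge graph — found by
Bron–Kerbosch with pivoting, emitted in sorted order. Degree tables
exclude the definitional self-loops. Circuit score is the mean planted
membership frequency of its members (fraction of circuits containing each
member); ranking is by descending score, ties to the larger circuit then
lexicographic members, and the top circuit is the representative CRC.
The score is a documented reconstruction of common practice for
representative-circuit selection, not a claim of equivalence to any
specific tool.

## Enrichment

One-sided hypergeometric upper-tail p per gene set (sets intersected with
the universe first), Benjamini–Hochberg adjustment across tested sets,
significance flagged at raw p ≤ 0.05 by default with the BH q reported
alongside. The universe defaults to all annotated genes and is
overridable.

## The synthetic-data generator

The generator emulates the statistical structure of the study design, not
its biology:

* **Genome** — i.i.d. bases at configurable GC (default 0.5, which makes
  uniform-background PWM p-values exact); genes on a ≥ 30 kb grid with
  random strand.
* **Peaks** — typical enhancers carry log-normal(μ=1, σ=0.1) signal with
  input ≈ 10% of sample; planted SEs are clusters of (default) 4
  constituents with gaps of 2 kb starting 5 kb downstream of the owner
  TSS, each constituent at the typical median × multiplier (default 10).
  Typical peaks are placed in disjoint slots that reserve a
  stitching-distance margin, so planted clusters are the only
  multi-constituent regions. σ = 0.1 was chosen because the tangent
  cutoff is only guaranteed to land at the planted block when the
  top-of-background order-statistic spacing stays below (score range)/n;
  with heavy-tailed background (σ ≈ 1) the tangent provably lands inside
  the background tail and planted/called sets cannot agree, which defeats
  the generator's purpose of providing exact planted truth.
* **Condition structure** — owner genes realise the configured
  model/treated counts and overlap (defaults 12/12 with 2 shared; the
  `study_scale` preset plants 403/77 with 36 shared). Typical peaks are
  identical across conditions; only planted ownership differs.
* **DEG table** — planted up-in-model genes get log2FC ~ N(+2, 0.25²)
  and q ~ U(0, 0.01); up-after-treatment genes the mirror image; nulls
  N(0, 0.25²) with q ~ U(0.2, 1). Exactly `candidate_overlap` up-in-model
  genes are lost-SE genes, and no gained-SE gene is up after treatment.
* **Expression** — candidates × samples (default 20/group, two groups),
  Gaussian FPKM with CV 0.15; the key gene's group means differ by 3
  within-group SDs, and two designated decoy genes by 1.5 SD. The decoys
  give the importance ranking a deterministic second and third place
  distinct from the similarity ranking's runners-up — the shape of a real
  importance plot — so the top-3 intersection isolates the key gene.
* **Ontology** — ≥ 30 terms under six branches; each non-key candidate
  gets two private leaves, the key gene is annotated with every candidate
  leaf (a strict superset, making it the mean-similarity maximiser), and
  two designated runner-up genes borrow a few leaves so the ranking below
  the key gene is stable.
* **Clique** — each clique member's model-condition SE receives (default)
  3 exact consensus insertions of every member's motif, planting a fully
  interconnected self-regulating circuit. All PWMs (clique and decoy TFs)
  are informative (consensus probability ≈ 0.97), keeping chance
  self-regulation negligible at p ≤ 10⁻⁴.

A self-audit re-verifies every manifest claim (constituent gaps, TSS
clearance, typical-peak separation, motif copies as exact substrings, set
sizes and overlaps) before a bundle is returned, and one integer seed
fixes every emitted byte via named RNG substreams.

What the generator does **not** emulate: read-level noise, fragment-size
and mappability artifacts, copy-number effects, realistic motif spacing
or composition, correlated expression structure, and background signal
whose tail overlaps the SE range. Passing the planted-truth tests
therefore shows that the algorithms implement their definitions correctly
and recover a clean planted signal — not that SE calls on real tissue
data would be equally unambiguous, where the rank curve's tail is smooth
and the SE/typical boundary genuinely fuzzy.

## Pipeline and determinism

One global seed fans out to per-stage seeds via a stage-name hash
(`(seed·1000003 + crc32(stage)) mod 2³¹`), so stages are individually
reproducible. All tables are written with deterministic row/column order
and shortest-round-trip float formatting; two runs from one seed are
byte-identical. Each stage writes a `.done` marker; with `--resume`,
stages with intact markers are skipped until the first missing one, after
which everything downstream reruns. A failing stage aborts with its name
and leaves completed outputs intact.

## Problem sizes

Defaults were sized for quick, well-powered checks: 12 planted SEs per
condition over 500 typical peaks on a 4 × 5 Mb genome; the
study-scale preset plants 403/77 SE genes (≈ 2,100 peaks, 8 × 5 Mb);
recovery rates use 20 seeds. The treated-condition up-regulated count in
the preset is kept at a reduced scale (100) since only the planted
overlap identities, not the DEG-table size, enter any downstream result.

## Known limitations

* The inflection cutoff is a point estimate with no uncertainty; near-tie
  geometries flip single regions across the boundary.
* Nearest-TSS assignment ignores topological domains and enhancer–gene
  contact data.
* The random forest is fit on whatever sample size the expression matrix
  offers; with very few samples per group (e.g. 3) the OOB curve is
  noisy and the MDG ranking unstable — the generator defaults to 20 per
  group for that reason, and real-data users should treat small-n
  rankings with caution.
* Motif scanning assumes an i.i.d. background; CpG bias or repeats will
  miscalibrate p-values on real genomes.
* Circuit scoring by membership frequency is one defensible choice among
  several; alternatives (total degree, expression weighting) are out of
  scope.
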