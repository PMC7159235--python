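# Methods

## Problem and model

`enloft` estimates, for every enhancer in a tissue-annotated enhancer→gene
regulation network, the probability that complete loss of the enhancer is
tolerated by the organism. The operational definition of enhancer loss of
function is deliberately conservative: only whole-element, homozygous
deletion counts. Partial deletions and SNV-mediated loss of activity are
out of scope because their functional impact cannot be called with
comparable confidence.

The underlying biological hypothesis is that tolerance is encoded in
network context: tolerant enhancers tend to be tissue-specific, regulate
few and dispensable genes, and sit in redundant regulatory neighborhoods
(their target genes receive input from many other enhancers), while
intolerant enhancers are broadly active, conserved, and wired to
indispensable genes. The classifier learns exactly this vocabulary.

## Coordinate conventions

All intervals are 0-based half-open (BED convention); VCF positions are
converted once, at the reading boundary. For a symbolic `<DEL>` record the
deleted span `POS..END` (1-based) maps to `[POS-1, END)`; explicit
left-anchored deletions (`REF=ACGT, ALT=A`) map to
`[POS-1+len(ALT), POS-1+len(REF))`. Multi-allelic records are split per
alternate allele; genotypes referencing another allele count as
non-carrier, which is the conservative choice for carrier counting. FILTER
handling is permissive by default (`pass_only` flag available) since no
filtering policy is intrinsic to the method.

## Curation rules

* **LoF-tolerant:** enhancer interval fully contained in a deletion that is
  homozygous in ≥1 sample and shares zero base pairs with any coding exon.
  Containment is closed under boundary equality ("100% deleted" read
  literally); exon overlap of a single base disqualifies.
* **Low-LoF-tolerance:** strictly >50% reciprocal overlap (both ratios)
  with an ultraconserved element. Reporter validation is an input flag on
  the conserved-element BED (name column), not something computable here.
* The two label sets must be disjoint; an enhancer qualifying for both
  (possible only on adversarial input) is excluded from both and logged.
* Enhancer length is deliberately **not** a feature: deletions are much
  longer than enhancers on average, but excluding length removes any
  residual bias toward short elements being easier to delete completely.

## Network and features

Undirected gene–gene interactions (restricted to the four direct kinds:
protein–protein, metabolic, phosphorylation, signaling) are stored as two
opposite directed edges, so degree counts neighbors once and path-based
centralities treat them symmetrically. Duplicate regulation rows collapse
with tissue-set union; edge weight is the tissue count.

Centralities are computed on the full heterogeneous graph, enhancer nodes
included. Solver choices (not dictated by the model, fixed here and
recorded in provenance): PageRank with damping 0.85 on the directed graph,
unweighted; eigenvector centrality on the undirected view (regulation
edges symmetrized for this metric only), which guarantees a Perron vector
and convergence; closeness over incoming shortest paths with the
reach-normalization that scores the middle of a 3-node path 1.0 and its
ends 2/3. Degree centrality is the fraction of other nodes a gene touches
(distinct neighbors). All of these are cross-checked in the test suite
against dense brute-force implementations (all-pairs BFS, power iteration)
on random graphs of ≤30 nodes at 1e-6.

All "v" aggregates use population variance (denominator *n*), matching the
printed EGTUv formula; an enhancer with one target has variance 0, not
missing. Per-tissue blocks are the enhancer's out-degree in each tissue
subnetwork and the mean subnetwork in-degree of its (full-network) target
genes, named `<tissue>__EOD` / `<tissue>__GIDa` for a stable, sortable
schema.

Feature pruning is greedy on Spearman |ρ| ≥ 0.9 (default; the cutoff is
config). Pairs are visited in alphabetical order and the later-named
column is dropped — deterministic, and biased toward keeping the canonical
global features whose names sort early. Explicit drop lists (e.g. a
redundant tissue block) are applied first. Missing entries (genes without
an indispensability score, enhancers without conservation) are imputed by
column median by default; zero-fill and row-dropping are available, and
every imputed cell is recorded in provenance.

## Classifier protocol

Positives greatly outnumber negatives, so each training repeat draws a
balanced batch (default 50 positives, paired with the full negative set),
searches hyperparameters (random search over trees/depth/features-per-
split/leaf-size, then a one-step local grid refinement), and scores each
candidate by stratified 10-fold CV mean AUROC with the same fold split
across candidates. Batches are consumed from reshuffled permutations of
the positive pool, so every positive is trained on whenever
repeats × batch-size covers the pool. The final model is the repeat with
the highest mean AUROC (ties: higher mean AUPRC, then lower repeat index),
refit on its full balanced sample. All randomness flows from one master
seed through per-repeat derived seeds recorded on each run.

The null-model check repeats the protocol with pseudo-negatives drawn from
unlabeled enhancers; a mean-of-means near 0.5 certifies that the small
negative set is not being memorized. Note that per-repeat values carry a
small upward selection bias (each is the best of several searched
configurations), so "near 0.5" means within roughly ±0.1.

Scores are the mean class-1 probability over trees. Thresholds: ≥0.5
binary tolerant call; >0.95 and <0.05 confident calls. Feature importances
are mean decrease in impurity, normalized to sum 1, reported per feature
and summed over four groups (gene, conservation, enhancer, edge features).

## Statistical analyses

* Tissue enrichment: per tissue, a 2×2 Fisher exact test of class vs
  non-class against in-tissue vs other-tissue counts. The default counting
  unit is enhancer–tissue *membership* (an enhancer active in k tissues
  contributes k units), which matches per-tissue percentage bars but
  clusters the units of one enhancer — its p-values are conservative under
  label randomization and should be read as descriptive. The alternative
  `distinct` unit partitions enhancers into active-in-t vs
  active-elsewhere-only; under random labels that table is exactly
  hypergeometric, which is the mode the calibration checks use. Zero cells
  get a Haldane–Anscombe +0.5 correction on the odds ratio only, flagged
  in the output.
* Two-sample KS uses the asymptotic p-value; the D statistic is verified
  against an O(n²) ECDF scan in tests.
* Rank-sum comparisons use exact enumeration for tie-free samples of ≤20,
  otherwise the tie-corrected normal approximation. Cohen's d uses the
  pooled SD; positive d means the first group is higher; zero pooled SD is
  reported as flagged rather than a number.
* Benjamini–Hochberg adjustment is the standard step-up procedure
  (delegated to statsmodels), validated against the manual computation.
* Disease-enhancer matching: overlap first, otherwise nearest enhancer on
  the chromosome by edge gap (ties → smaller start); a match is kept only
  if the reported target gene is among the matched enhancer's regulated
  genes; cancer-typed rows are excluded to avoid somatic-variant elements.
* Motif presence: log-odds PWM scan against a uniform background
  (pseudocount 0.5), both strands, threshold 80% of the motif's maximum
  achievable score. The threshold policy is config and echoed in output;
  external motif matchers use their own defaults, so absolute presence
  fractions are comparable only within a policy.

## Synthetic universe

The generator emulates the statistical structure the method exploits, not
real genomes. Defaults (chosen once as a desk-scale but non-trivial
condition): 2,000 enhancers and 600 genes on two 10-Mb chromosomes, 15
tissue groups, 60 samples in three population groups, 10% tolerant-like /
4% low-tolerance-like / 2% held-out tolerant-like enhancers,
`signal_strength = 3`. Enhancers occupy disjoint slots, which makes label
geometry unambiguous: each tolerant-like enhancer is covered by a
homozygous, exon-free deletion confined to its slot; decoy deletions are
het-only, partial, or exon-overlapping; each low-like enhancer reciprocally
overlaps a conserved element, with partial-overlap and reporter-negative
decoys. Class-conditional draws (target-gene pools and their GIS, per-edge
tissue counts, preferred tissues, conservation, planted POU-like motifs)
separate in the directions observed in real data, with separation scaled
by `signal_strength`; at 0 every class distribution is identical. The
held-out tolerant-like class receives no base deletion; a companion
generator emits long-read-style novel deletions (each overlapping every
base deletion by <80% of either interval) that cover exactly those
enhancers, enabling the discovery-style end-to-end check.

What passing these tests does **not** show: real enhancer catalogs have
overlapping elements, length-correlated deletion detection, linkage
structure, non-uniform sequence composition and incomplete genotyping —
none of which the generator reproduces. Results on the synthetic universe
validate the machinery and its implementation, not biological effect sizes.

## Problem sizes used in the checked runs

The test suite and worked examples run the protocol at reduced scale as
the package's own desk-scale configuration: training with 2–5 repeats and
a search budget of a few configurations on the 2,000-enhancer universe,
and the end-to-end determinism check on a 400-enhancer universe with 2
repeats. The API defaults remain the full protocol (50 repeats × 50
positives, 10 folds). Determinism is byte-level: identical seed and config
reproduce identical text artifacts.

## Known limitations

* Eigenvector centrality on a disconnected graph reflects the dominant
  component; the symmetrized view makes convergence reliable but is an
  approximation for strongly asymmetric regulation structures.
* Probabilities are raw tree means, not calibrated; thresholds (0.5,
  0.95/0.05) are conventions, not decision-theoretic optima.
* The Spearman-pruning order is name-dependent by design; renaming columns
  can change which of two redundant features survives.
* Fisher p-values on sparse tissues are discrete and conservative;
  enrichment odds ratios with corrected zero cells should be read
  qualitatively.
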