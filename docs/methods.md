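# Methods

## Annotation propagation

Annotations obey the true-path rule: a gene annotated to a term is
implicitly annotated to every ancestor reachable over `is_a` and
`part_of` edges. Only these two relation types propagate;
`regulates`-family and other relationship lines are parsed and retained
in the typed graph but do not enter the closure (standard GO curation
practice). Obsolete terms are kept as flagged records with no edges, and
annotations naming unknown or obsolete terms are dropped; if more than
5% of rows drop (configurable), the run aborts, since that usually means
mismatched ontology/annotation releases. Evidence codes are all retained
by default (including IEA); a whitelist filter exists. Gene identity is
the GAF `DB-Object-Symbol` column, case-sensitive, so isoform-level
DB-Object-IDs with one symbol collapse to one gene.

## Term network

The projection T = w′B′Bw with w = diag(1/k_i) is computed from integer
shared-gene counts divided once per pair, so T is symmetric bit-for-bit
and each weight is the exact float of an integer ratio. The raw
projection has diagonal T_ii = 1/k_i; the diagonal is zeroed before
community detection (a self-loop only inflates a node's own-community
term and its strength, distorting the null model) and kept as a sidecar
array so either convention can be audited. Namespace-restricted
networks are re-projected from the restricted incidence, not sliced out
of T, so the k_i in the denominator are recomputed on the subset.

## Community detection

Modularity uses the resolution-generalized null factor (1 + r/⟨k⟩)
applied to the weighted configuration-model term k_i k_j/(2m), with
"degree" read as node strength and m as total edge weight. ⟨k⟩ is a
property of the input graph, computed once and not updated during
agglomeration. The optimizer is a weighted CNM fast greedy: start from
singletons, repeatedly merge the *connected* community pair with the
largest ΔQ (merging disconnected communities is never beneficial for
r ≥ 0), record every merge, and cut the dendrogram at the maximum-Q
step. Determinism is guaranteed by explicit tie rules: among equal-ΔQ
candidates the lexicographically smallest community-index pair merges
first, the merged community keeps the smaller index, and on Q plateaus
the earliest step (most communities) wins. Candidate ΔQ values live in
a lazy heap; stale entries are detected by exact recomputation at pop
time, which is safe because an unchanged pair recomputes to a
bit-identical float. At r = 0 the procedure reproduces igraph's
weighted fast-greedy modularity to ~1e-15 on random graphs (checked in
the test suite).

The resolution sweep runs the greedy at each r of a configurable grid
(default: r = 0 plus a geometric grid over 0.01–100) and registers each
distinct member set once under a `TC:%07d` id, recording every
resolution at which it appeared. Comparable partitions at the full
GO scale are tie-break sensitive: two implementations can differ in
exact community counts while agreeing in modularity, which is why only
desk-scale quantities are asserted by the test suite.

## Comparison and word clouds

J_m is computed only among sets with ≥ 10 members on both sides
(Jaccard is unstable for tiny sets); best-match ties go to the smaller
counterpart, then the lexicographically smallest id. The overlap graph
links a finer-resolution community to a coarser one when ≥ 10% of the
finer community's members lie in the coarser one; node size is
log(member count) and node color is the per-domain member fraction
divided by that domain's global share of terms (BP dominates raw
counts) and renormalized to sum 1.

Word clouds treat token *occurrences* as the urn: the group's n token
occurrences are a draw from the N background occurrences (all
non-obsolete term names, all three domains), and each word's p-value is
the exact hypergeometric upper tail of its group count. Size score is
−log10(p) with a 1e-300 floor. Tokenization lowercases, splits on
whitespace and light punctuation (`,/():[]`), strips edge punctuation,
keeps internal hyphens ("nucleotide-excision" is one token), and drops
tokens under two characters; there is no default stopword list (generic
words like "cellular" legitimately appear and are down-weighted by the
enrichment itself). Settings are snapshotted into every spec. Color
mixes subtractive primaries — BP yellow, MF cyan, CC magenta — on
per-domain occurrence rates normalized by the domain's background
occurrences and rescaled to peak 1, so a single-domain word is a pure
primary and equal normalized rates give black.

## Annotation enrichment analysis

The statistic for a (signature, term group) pair is the annotation-edge
count S = Σ_{p∈genes, i∈terms} B_pi. The null preserves both degree
sequences of B via double edge swaps: a sample applies 10×|edges| swap
attempts to a fresh copy of the observed edge list (rejecting swaps
that would collide or create multi-edges), and S is recomputed per
sample. Independent restarts per sample — rather than one long chain
sampled periodically — keep null draws i.i.d.; during development the
chained variant showed measurable serial correlation between the
observation and nearby null draws, visibly distorting null p-value
uniformity, and was rejected. The empirical p-value is
(1 + #{S_null ≥ S}) / (1 + n_rand), never zero. The swap sampler is
isolated behind `BipartiteNullEngine` so alternative degree-aware nulls
can be swapped in. No multiple-testing correction is applied by
default (results are reported at raw cutoffs 0.01 / 0.001); a BH pass
is left to the caller. Cells of the signatures × groups grid get
independent `SeedSequence`-derived sub-seeds, so the grid is invariant
to evaluation order.

Because S is integer-valued, the empirical p-value is exactly uniform
under the null only up to ties; the calibration check therefore uses a
world sized so the null spread of S (sd ≈ 10 counts) makes ties
negligible at n_rand = 99. The Fisher baseline is the classic one-sided
2×2 test (signature membership × annotated-to-group) over the annotated
gene universe; with degree-biased signatures it over-rejects by an
order of magnitude while AEA stays at level — the motivating contrast
for the degree-aware null.

## Synthetic worlds

The generator emulates the statistical regime the method targets, not
real GO topology. Ontologies are layered random DAGs: one root per
namespace, depth strata, each non-root term drawing one (70%) or two
(30%) parents from the stratum above, names sampled from a fixed
biological vocabulary. Annotations plant a block structure: genes and
leaf terms are split round-robin into blocks (default 4), direct
annotations are Bernoulli with p_within = 0.3 inside and
p_between = 0.005 across blocks, and each leaf term carries a Pareto
(tail index 1.5, capped at 50×) propensity multiplier so term degrees
are heavy-tailed — the regime that motivates the inverse-degree
weighting. An optional per-gene Pareto multiplier
(`gene_tail_exponent`) produces the heavy-tailed gene degrees needed
for the Fisher contrast. Signatures oversample a target block's genes
(80% by default) or sample uniformly for nulls. All generators are
pure functions of (config, seed), and written OBO/GAF/GMT files
round-trip exactly through the package's own parsers.

Presets: `tiny` (60 terms / 80 genes, CLI smoke tests), `small`
(200 terms / 240 genes / 4 blocks; the default study condition),
`large` (2000 terms / 3000 genes / 8 blocks). What passing tests on
these worlds show is that the machinery is correct and calibrated under
planted ground truth; they do not show that real GO communities are
biologically meaningful, that annotation biases beyond degree
heterogeneity are handled, or how tie-breaking interacts with the
quasi-degenerate modularity landscape of the full term network.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as
the smallest sizes at which each property is statistically decidable:
brute-force projection checks on ≤50×50 incidences, exhaustive
partition search on ≤10-node graphs, 20-seed recovery ensembles,
1000-trial null calibration at n_rand = 99, 200-trial Fisher contrast
at n_rand = 199. Merge bookkeeping is asserted to 1e-10 against direct
re-evaluation; projection and best-match checks are exact. The
compendium-scale path (tens of thousands of terms) is provided as
`scripts/replicate_full_data.py`; its memory and time cost comes from
the closure-dense B′B product and the near-quadratic agglomeration, and
exact community counts there are tie-break sensitive.

## Known limitations

* The agglomeration is O(n·m·log n)-ish in pure Python; the full GO
  network is feasible but slow (hours), and no Louvain/Leiden-style
  alternatives are provided by design.
* The swap-chain null assumes 10×|edges| attempts suffice to decorrelate
  a sample from the data; for very dense incidences more attempts may be
  needed (configurable via `swaps_per_edge`).
* Cross-domain GO relationship lines are parsed but never propagated or
  analyzed.
* The word-cloud output is a data specification; no layout or rendering
  is included.
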