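# Methods

## The statistical model

`koenrich` performs over-representation analysis (ORA): given a foreground
gene list (e.g. differentially expressed genes) drawn from a background
list, it asks for each KEGG pathway whether the foreground contains more
pathway members than a random draw would. Conditional on the lists, the
number of foreground pathway members k follows a hypergeometric
distribution with parameters (N, K, n): N universe genes, K of them in the
pathway, n foreground genes. The reported p-value is the upper tail
including the observed count,

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N, n),

equivalent to R's `phyper(k-1, K, N-K, n, lower.tail=FALSE)` and to the
one-sided ("greater") Fisher exact test on the 2x2 table
[[k, n-k], [K-k, N-K-n+k]] — the test suite asserts both equivalences
against independent implementations. The tail is summed in log space with
lgamma-based binomial coefficients, which keeps the computation stable for
universes around 10^4 genes and p-values down to ~1e-300.

**Universe convention.** N counts the background genes annotated to at
least one pathway; background genes with no pathway annotation carry no
information for a membership draw and are excluded. Likewise, n counts
foreground genes inside that universe. Foreground genes absent from the
background are dropped with a warning. All drop counts are logged and
written to the run manifest, because this choice changes N and therefore
every p-value.

**Counting level.** A gene contributes at most 1 to a pathway's count no
matter how many of its KOs belong to the pathway (gene-level semantics).
The KO-level detail is kept as per-link provenance and used only when
painting pathway diagrams, where nodes are KOs, not genes.

**Multiple testing.** BH step-up adjusted p-values are computed across
exactly the set of tested pathways: every pathway with K >= 1 in the
universe, including those with k = 0 (which get p = 1). The optional
`--drop-empty` flag restricts the family to k >= 1, changing m; the
default includes k = 0 pathways because the family of hypotheses is "all
pathways represented in this universe", not "all pathways the foreground
happened to hit".

**Thresholds.** Significance filtering uses strict `<` with defaults of
0.05 for both raw and adjusted p. `alpha = 1.0` is treated as "no filter"
(retaining records with p exactly 1), since a vacuous threshold is its
only sensible meaning under strict comparison.

## Annotation handling

Three input dialects are parsed: eggNOG-mapper v2 annotation tables
(`##` comments, `#query` header, the `KEGG_ko` column located by name,
cells `-` or comma-separated `ko:Kxxxxx`), and plain two-column
`gene<TAB>KO` tables as exported by BlastKOALA and KAAS. KO tokens are
normalized by stripping an optional `ko:` prefix and upper-casing; any
token not matching `K` + 5 digits afterwards is a hard format error —
failing fast beats silently losing annotations. Up to three sources merge
by union ("sum of annotations") or intersection ("minimum") of (gene, KO)
pairs; pair-level rather than gene-level semantics is the most literal
reading and makes both merges associative, commutative and idempotent
(property-tested). Pathway ids accept the spellings `path:ko00010`,
`map00010` and `ko00010`, all normalized to `ko00010`. Overview-style
pathways are not excluded automatically; `--exclude-pathways FILE` removes
a user-supplied list before the universe is derived.

## Visualizations

Every plot is split into a pure data-builder returning a serializable
payload (used for golden and determinism tests) and a renderer. Choices
where the design was open:

- **Treeplot**: pairwise term distance 1 − Jaccard on member-gene sets,
  average-linkage agglomerative clustering. Jaccard-on-genes is the
  conventional term-similarity family for ORA results and requires no
  external ontology.
- **Cnetplot**: bipartite pathway-gene graph, seeded force-directed
  (Fruchterman–Reingold) layout; node positions are part of the payload
  so renders are reproducible given the seed, which is recorded in the
  HTML output.
- **UpSet**: exclusive intersection semantics — each gene is counted in
  exactly one pattern, the full combination of sets containing it, so
  pattern counts partition the union.
- **Top-n**: bar/lollipop/cnet/upset default to the 20 best-ranked
  pathways to stay legible; the TSV always carries the full table.
- **HTML output** is a self-contained document embedding the base64 PNG
  and the payload JSON — no remote assets, openable offline.
- **KGML diagrams**: entries are matched at KO level via the `ko:Kxxxxx`
  tokens in each entry's `name` attribute; an entry is painted red when
  its KOs intersect the KOs carried by the enriched genes (from the
  term2gene provenance). The canvas is rebuilt from the KGML graphics
  coordinates (y axis inverted; KGML's origin is top-left).
- Both a raw-p and an adjusted-p variant of every selected plot are
  produced per run.

## The synthetic-data generator

`SpikeDesign` emulates a draft-genome KO annotation study:

- Pathways draw their KO sets from a shared pool sized at 80% of the
  summed pathway sizes, so pathways overlap as KEGG maps do; a further
  30% of the pool are KOs belonging to no pathway, so part of the
  annotated background falls outside the test universe (as with real
  draft annotations, where many orthologs carry no pathway assignment).
- Each gene draws 1–3 KOs uniformly from the pool (default range).
- The foreground is sampled conditional on the lists — no expression or
  read-level noise model — either uniformly (null design) or stratified:
  a `spike_fraction` share is drawn from the member genes of the spiked
  pathways, the rest uniformly from the remainder. A design whose spike
  exceeds the spiked pathways' member capacity is rejected as infeasible.
- The truth manifest (TSV) names the spiked pathways with their realized
  (k, n, K, N), recomputed through the same universe derivation the test
  uses, so checks never reach into generator internals.
- Defaults are the draft-genome demo scale: 12 134 background genes,
  437 foreground, 150 pathways.

What passing tests on this generator do **not** show: robustness to
annotator error profiles (wrong or missing KO assignments), to pathway
size biases of real KEGG releases, or to correlated gene sets from
co-expression — real data differ in all three.

### Calibration of the null design

The hypergeometric test is discrete, so its attained size is below the
nominal 0.05. The null study used for type-I checks (2 000 genes, 50
pathways of 10–30 KOs, 200-gene foreground) was designed so pathways have
K ≈ 60–90 universe members, giving enough p-value resolution: the
attained level, computed analytically from the hypergeometric CDF at the
design stage, is ≈ 0.035. The empirical fraction of p < 0.05 over 500
seeded replicates matches it. The power study uses fewer, larger pathways
(20 pathways of 15–30 KOs, 100-gene foreground, half drawn from one
spiked pathway) so that the spiked pathway always has enough member genes
to cover the spike.

## Numerical and formatting choices

- p-values are clipped into (0, 1]; k = 0 returns exactly 1.
- BH is delegated to `statsmodels` and verified against the direct
  step-up formula on random vectors.
- Result rows sort by (adjusted p, raw p, pathway id) — the id breaks
  ties deterministically. Reals print with 9 significant digits;
  ratios print as `k/n` and `K/N`.
- Problem sizes in the validation suite (replicate counts of 500/200,
  enumeration up to N = 30, 2 000-gene replicate studies) were chosen to
  give tight Monte-Carlo error on a single CPU within a few minutes.

## Known limitations

- Only KEGG-pathway-style catalogs; no GO terms, no GSEA-style ranked
  statistics, no permutation nulls.
- Live KEGG/PubMed access is out of scope by design: catalogs, KGML
  files and publication counts are always supplied locally (the
  PubMed-trend plot takes injected year → count data).
- KGML rendering rebuilds a schematic canvas (boxes at the recorded
  coordinates), not KEGG's full cartoon artwork.
- One catalog release per run; comparing KEGG releases is up to the user.
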