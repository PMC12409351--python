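# Methods

This note documents the models and procedures implemented in `panphage`,
the defaults and why they were chosen, the design decisions taken where
the design was genuinely open, and what the synthetic-data experiments do
and do not demonstrate.

## Encodings

All three pangenome–phage interaction matrices share one container: a
binary entity × strain matrix in which every row carries a category
(`bacterial_gene`, `phage`, `phage_gene`). Bacterial gene rows pass
through every builder unchanged; the strain order of the GPA matrix is
the canonical axis and host-range columns are permuted to it.

* plus: phage row = infection pattern; plus and minus rows of the same
  phage sum to the all-ones vector by construction.
* minus: phage row = complement of the infection pattern.
* plus-genes: one row per phage gene family, the boolean OR of the
  carriers' infection rows; consequently a family row dominates
  (entrywise ≥) the plus-encoding row of every carrier phage.

The builders accept any complete binary phage × strain matrix, so
adsorption matrices (or "adsorbs but does not infect" matrices) are
analysed by re-labelling the input; the computation is identical, which
is why the CLI exposes only an `--interaction-label` cosmetic flag.
Continuous infection measures (plaque size, efficiency of plating) must
be discretised upstream; the method consumes a discrete classification
only.

Phage identifiers are namespaced with a configurable suffix (default
`_Phag`) at read time so they can never collide with gene identifiers
after the join. Entities that are constant across strains (all 0 or all
1) carry no events; they are retained by the builders and removed by
`filter_entities` (defaults: present in 1..n−1 strains) with a logged
list, so phages absent from the results are explainable.

## Ancestral reconstruction and events

Presence states at internal nodes are reconstructed by Fitch small
parsimony, applied to all entities at once over 2-bit candidate-set
masks. Determinism is guaranteed by two rules: an ambiguous root resolves
to *absent* (accessory genes and phage susceptibilities are typically
rare, derived states), and every other node inherits its parent's state
whenever that state is parsimony-optimal for it. The assignment always
attains the minimum parsimony score (verified exhaustively against a
brute-force labeling oracle in the test suite), so the event count per
entity equals its parsimony score and at most one event occurs per
branch. A likelihood-based reconstruction is deliberately out of scope;
the configuration key `ancestral_confidence` (default 0.999) is reserved
for such a mode and has no effect under parsimony.

Polytomies are resolved deterministically into caterpillars of
zero-length branches, combining children in lexicographic order of their
labels (internal children labelled by their smallest descendant leaf).
Zero-length branches receive zero weight in the null model, so artificial
edges can never host simulated events. Missing branch lengths are read as
zero with a warning rather than rejected, which makes cladogram-like
inputs loadable while keeping them inert in the null.

## The association test

For entities *i* and *j* with event sets on the same tree:

* simultaneous score = #branches where both gain + #branches where both
  lose;
* dissociation score = #branches where one gains and the other loses.

Null model (conditional placement): entity *i*'s events are held fixed;
entity *j*'s observed numbers of gains and losses are kept but their
branch locations are redrawn without replacement with probability
proportional to branch length (Gumbel top-k sampling, equivalent to
sequential weighted draws), and which of the drawn branches carry gains
is uniform over subsets. Conditioning on the per-entity event counts
removes gene-frequency confounding, and the scheme admits an exact
enumeration oracle on small trees, against which the sampler is tested.
Both score types are computed from the same placement samples.

p-values are one-sided with add-one smoothing, p = (1 + #{null ≥
observed})/(g + 1), so p ≥ 1/(g+1) > 0 and the test is a valid Monte
Carlo test. Pairs with observed score 0 receive p = 1 without simulation.
Benjamini–Hochberg correction is applied separately per score type with
the family counting *all* eligible pairs, including the score-0 ones;
significance means q ≤ `fdr_alpha` (default 0.05). Raw p-values are
reported alongside q-values in the pair table.

Defaults: `null_samples` g = 50 000 per cached null configuration;
`min_events` = 2 (an association requires a repeated joint pattern, so
entities gained/lost fewer than twice are excluded); `coincidence` =
both. Placements are generated once per (gains, losses) configuration
and scored distributions cached per (fixed-event-set signature, gains,
losses); per-key seed substreams are derived from the master seed by a
stable hash, so results are independent of pair iteration order and
identical with or without the cache. For each unordered pair the entity
that sorts first lexicographically is the fixed one, making results
symmetric in the pair.

Properties and caveats:

* The score is a small discrete statistic, so the empirical p-values are
  *conservative*: P(p ≤ α) equals the null tail probability at the
  largest attainable level ≤ α, which for typical event counts is well
  below α (measured ≈ 0.015 at α = 0.05 for neutral genes on a 50-leaf
  tree). Type-I error is controlled, but the p-value distribution is not
  uniform and cannot be for any discrete test with this p-value
  convention.
* Monotonicity: for a fixed null, p is non-increasing in the observed
  score.
* The `--threads` CLI option is reserved; the computation is serial and
  its result does not depend on the option's value.

### Statistical resolution of a scan

With t true pairs at the Monte-Carlo floor p = 1/(g+1) among m eligible
pairs, the smallest BH-adjusted value they can attain is m/((g+1)·t).
A validation scan (or a real analysis) therefore needs g large enough
that this quantity clears the significance threshold — e.g. six true
pairs among ~12 000 eligible pairs need g ≳ 50 000 at q ≤ 0.05. The
end-to-end test scenarios in this package (60 strains, 150 genes, six
phages, g = 50 000) were sized by this calculation.

## Clustering and network export

Markov clustering (MCL) is implemented once (dense numpy) and shared by
the association network and the phage gene families: column-stochastic
adjacency with self-loops, expansion power 2, entrywise inflation
(default 2, matching the phage-gene clustering convention), pruning of
entries < 1e-5, convergence when the iterate changes by < 1e-6, at most
100 iterations. Clusters are read from attractor rows; overlaps are
merged and every node is assigned to exactly one cluster (ties to the
lowest node id). Disconnected components are never merged. The clustering
operates on the unweighted graph of significant association pairs;
dissociation pairs are exported as a distinct edge kind and never enter
the clustering, because clusters summarize co-occurrence.

Cluster centres exist for clusters of ≥ 2 members; singletons stay bare
nodes. A centre is `mixed` when its members span ≥ 2 categories. The
inter-cluster force is 1 + f with f = (significant cross pairs)/(|A|·|B|)
counting all entity pairs regardless of category, added when f > 0, so
1 < force ≤ 2 and force = 2 iff every cross pair is significant. The
default display threshold 1.1 corresponds to ≥ 10% of cross pairs
associated. The `mixed-only` view keeps mixed clusters plus clusters
connected to them by a retained inter-cluster edge. Export is
deterministic (sorted node/edge insertion; byte-identical GraphML for
identical inputs), with attribute values sanitized of tabs/newlines.

## Phage gene families

The similarity prefilter is either a precomputed 12-column tabular hit
file (best e-value per unordered pair < 0.1; the e-value semantics belong
to the external search tool that produced the file) or, for ≤ 2000 genes,
exhaustive enumeration. Global identity is computed with Needleman–Wunsch
under BLOSUM62, gap open 10, gap extend 0.5 — the cited global aligner's
conventional defaults — with end gaps penalized (a conservative, truly
global family definition; end-gap-free variants would merge more
length-discordant pairs). Identity = 100 · identical columns / alignment
length including gap columns, which is the convention under which the
80% cutoff is defined; the threshold is sharp (≥ 80). Families are the
MCL clusters of the ≥ 80% identity graph; isolated genes become
singleton families; family ids are deterministic (size descending, then
smallest member).

## Synthetic data

What the generator emulates:

* `simulate_tree` — Yule pure-birth trees (rate 1) with exponential
  branch lengths; expected total length ≈ n, so event-rate choices below
  translate directly into expected event counts.
* `simulate_neutral_genes` — independent two-state Markov chains with
  gain and loss rates (defaults 0.1/0.1: ≈ 5 expected events per gene on
  a 50-leaf tree, the regime of repeatedly mobile accessory genes the
  method targets); root states are stationary. Branches are simulated
  through the chain's exact transition probabilities, so recorded truth
  events are per-branch *net* changes — double flips within one branch
  are invisible, exactly as they are to parsimony.
* `plant_associated_pairs` — a partner gene copies each template event
  with probability ρ and keeps its own with probability 1 − ρ; leaf
  states are regenerated by treating events as toggles. ρ = 1 yields an
  identical history and leaf pattern. Template eligibility is judged on
  parsimony-inferred events, since that is what detection operates on.
* `simulate_host_range` — receptor mode: infects ⇔ receptor present;
  defense mode: infects ⇔ defense absent; both: receptor present AND
  defense absent; then independent per-cell flips with probability ε.
  The single-factor modes exist so each encoding's claim can be tested
  in isolation (at ε = 0 the plus row equals the receptor row and the
  minus row equals the defense row exactly); driver genes are drawn from
  genes with ≥ 3 parsimony events because detection requires repeated
  joint gains/losses.
* `simulate_phage_genomes` — per-phage private gene families plus a
  marker family shared by phages with the same receptor; sequences are
  template proteins (length 120) with per-site substitution probability
  0.03, keeping within-family identity above and between-family identity
  below the 80% cutoff (verified with the aligner post hoc, not assumed).

What it does not emulate — and hence what passing tests do not show about
real data: no horizontal co-transfer mechanism (planted pairs are copies,
not a transfer model), no recombination, no rate heterogeneity across
genes or branches, no partial/continuous infection phenotypes, no
correlated noise in host-range assays, and no attempt to mimic any real
dataset's size or frequency spectrum. Recovery of planted receptors at
ε = 0 demonstrates correctness of the machinery, not expected sensitivity
on noisy experimental matrices.

## Numerical and degenerate-input choices

* Binary validation is strict: any non-binary or missing cell aborts
  before computation, naming the offending row and column.
* All-zero phage rows (or all-one rows in the minus encoding) are legal
  inputs, logged, and removed by the frequency filter before testing.
* A tree whose positive-length branches are fewer than an entity's event
  count cannot host the null placement and raises an error.
* MCL non-convergence at `max_iter` warns and uses the current state.
* Ties everywhere resolve by fixed rules (lexicographic labels, lowest
  node id, stable sorts); no operation depends on dict iteration order
  or platform randomness.

## Known limitations

Interactions involving core genes are invisible (no events), as are
genes confined to one or two clades (too few events); detection requires
phages whose host range spans several independent gains/losses across
the phylogeny. Parsimony underestimates events on long branches. The
conditional null holds one entity fixed, which tests dependence given
both entities' event counts but does not model joint transfer rates. BH
controls the FDR on average; individual neutral pairs can and do fall
below planted pairs in the q-ranking at the nominal rate.
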