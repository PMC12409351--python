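# panphage

Phylogeny-aware association of phage host range with bacterial accessory
genes.

## The problem

Whether a phage can infect a bacterial strain is largely decided by
accessory genes: surface receptors that let the phage adsorb and enter,
and defense systems (restriction–modification, CRISPR/Cas, abortive
infection, ...) that block it. Both kinds of genes ride on mobile elements
and are gained and lost repeatedly across a species. Given

1. a pangenome gene presence/absence (GPA) matrix (genes × strains, from
   Panaroo/Roary-style tools),
2. a rooted strain phylogeny (Newick), and
3. a **complete** binary host-range matrix (phages × strains),

`panphage` finds bacterial genes whose presence — or absence — is
statistically associated with phage infectivity, beyond what shared
ancestry explains. It is aimed at microbial genomicists designing
phage–host experiments and at anyone studying gene co-occurrence in
pangenomes.

## The method

Phage infectivity is re-encoded as pseudo-gene rows of the GPA matrix:

* **plus** encoding — a phage row is 1 where the phage infects: detects
  genes whose *presence* enables infection (receptor candidates);
* **minus** encoding — a phage row is 1 where the phage does **not**
  infect: detects genes whose presence prevents infection (defense
  candidates);
* **plus-genes** encoding — one row per phage gene family, present in the
  strains infected by a carrier phage: links bacterial genes to particular
  phage genes. Families are built from protein sequences (global
  Needleman–Wunsch identity ≥ 80%, Markov clustering with inflation 2).

For every entity (gene, phage, phage gene family) ancestral presence
states are reconstructed on the phylogeny by Fitch parsimony and each
state change on a branch becomes a gain (0→1) or loss (1→0) event. For a
pair of entities *i, j* the association statistic is the **simultaneous
score** — the number of branches where both gain or both lose — and the
**dissociation score** counts opposite-direction coincidences. Its null
distribution is simulated by redrawing entity *j*'s observed numbers of
gains and losses onto branches sampled without replacement proportionally
to branch length (*g* = 50 000 samples by default); empirical p-values
p = (1 + #{null ≥ observed})/(g + 1) are corrected per score type by
Benjamini–Hochberg over all eligible pairs, with significance at
q ≤ 0.05.

Significant associations form a network that is partitioned by Markov
clustering; each cluster is summarized by a centre node, and centres are
linked with attribute `force = 1 + (significant cross pairs)/(|A|·|B|)`,
so a threshold of 1.1 keeps cluster pairs with ≥ 10% of all possible
cross pairs associated. The network is written as GraphML (for Cytoscape)
plus flat TSV tables.

A synthetic-data module generates Yule trees, gene content evolving by a
two-state gain/loss chain, planted co-occurring pairs, receptor/defense
driven host ranges with noise, and synthetic phage proteomes — so every
claim is testable against known ground truth without downloads.

## Worked example

Simulate a 60-strain, 150-gene pangenome with six phages whose host range
is driven by receptor genes, then run the full pipeline:

```sh
panphage simulate --out demo --strains 60 --genes 150 --phages 6 \
    --mode receptor --seed 11
panphage build-matrix --gpa demo/gpa.Rtab --host-range demo/host_range.tsv \
    --mode plus --out demo/gpa_plus_phage.Rtab
panphage associate --matrix demo/gpa_plus_phage.Rtab --tree demo/tree.nwk \
    -g 50000 --seed 1 --out demo/pairs.tsv
panphage network --pairs demo/pairs.tsv --force-threshold 1.1 --out demo/net
```

The `associate` step prints

```
 score_type category_pair  significant_pairs
association    gene-phage                  6
wrote 22350 tested pairs to demo/pairs.tsv
```

and the top of `demo/pairs.tsv` reads

```
entity_a  entity_b  category_a  category_b      score_type   observed_score  p_value       q_value
P1_Phag   g121      phage       bacterial_gene  association  4               1.99996e-05   0.03725
P2_Phag   g11       phage       bacterial_gene  association  3               1.99996e-05   0.03725
P3_Phag   g146      phage       bacterial_gene  association  3               1.99996e-05   0.03725
```

All six significant pairs are phage–receptor pairs, and they match the
generator's ground truth exactly (`demo/truth.json` records
`P1 → g121, P2 → g11, P3 → g146, ...`): each phage's infection pattern
was gained and lost together with its receptor gene 3–4 times along the
phylogeny, the p-value 2.0·10⁻⁵ is the Monte-Carlo floor 1/(g+1), and
q ≈ 0.037 after BH correction over all 22 350 eligible pairs per score
type. `demo/net.graphml` contains the corresponding six two-member
clusters for Cytoscape.

## Layout

| Module | Role |
| --- | --- |
| `panphage.io_formats` | readers/writers + typed containers (matrices, tree, proteins) |
| `panphage.matrix_builder` | plus / minus / plus-genes encodings, frequency filter |
| `panphage.ancestral` | polytomy resolution, Fitch reconstruction, event extraction |
| `panphage.association` | pair scores, simulated null, empirical p, BH, full scan |
| `panphage.network` | MCL core, cluster-centre network, force filter, GraphML export |
| `panphage.phage_genes` | candidate pairs, global identity, gene family clustering |
| `panphage.simulate` | synthetic trees, pangenomes, host ranges, phage proteomes |
| `panphage.cli` | `panphage` command with the subcommands used above |

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
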