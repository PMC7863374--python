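# microbeta

Beta-diversity analysis of 16S OTU count tables, built around two
complementary distance metrics and the statistics needed to relate community
composition to host metadata:

- **Curation** — read screening (ambiguous bases, homopolymers, length
  window), rarefaction without replacement, rare-OTU filtering, and
  subset-with-pruning.
- **Diversity** — Shannon and Berger-Parker alpha diversity; weighted,
  branch-length-normalized **UniFrac** on a rooted OTU phylogeny; and an
  exact **Earth Mover's Distance** over phylum-structured color histograms
  (OTUs map to bins in the RGB unit cube, same-phylum bins deliberately
  closer than cross-phylum bins, transport solved as an exact LP — no
  image rendering, no approximation).
- **Ordination** — PCoA via Gower double-centering, and partial constrained
  ordination: Z-scored OTU abundances, a covariate block (host-species
  dummies) partialled out, a single quantitative constraint (days in
  captivity), permutation pseudo-F with per-OTU **FitE** scores (percent
  variance explained).
- **Stats** — ANOSIM, Mann-Whitney on pairwise distances, phylum enrichment
  of top-FitE OTUs vs background, chi-square goodness of fit, fold
  enrichment, Spearman correlation.
- **Synthetic data** — a Dirichlet-multinomial community generator matched
  to the analysis: Firmicutes-dominated low-Bacteroidetes communities,
  strong inter-sample heterogeneity, a captivity covariate that expands a
  designated set of Actinobacteria OTUs, technical-replicate resampling,
  and a heterogeneity-tuning helper. All outputs deterministic per seed.
- **Pipeline** — YAML-configured end-to-end run with per-stage seeds, TSV
  side files and a JSON report; PCoA plotting helpers.

Formats supported: plain-TSV and mothur-"shared" feature tables, two-column
semicolon-lineage taxonomy, Newick trees (branch lengths required), square
TSV and PHYLIP square distance matrices, TSV metadata, FASTA reads.

## CLI

Everything is reachable through the `microbeta` entry point:

```bash
# simulate a dataset and write its four artifacts
microbeta simulate --seed 7 --out sim/

# read screening
microbeta curate --reads reads.fasta --out kept.fasta --max-homopolymer 8 --max-ambig 0

# rarefy + filter a table
microbeta tablefilter --table sim/table.tsv --out filtered.tsv --depth 5000 --min-otu-total 10 --seed 1

# beta diversity
microbeta betadiv --metric emd --table sim/table.tsv --tax sim/taxonomy.tsv --out dm_emd.tsv
microbeta betadiv --metric wunifrac --table sim/table.tsv --tree sim/tree.nwk --out dm_wu.tsv

# ordination
microbeta ordinate pcoa --dm dm_emd.tsv --axes 3 --out coords.tsv
microbeta ordinate cca --table filtered.tsv --meta sim/metadata.tsv \
    --constraint days_in_captivity --covariate species_code --perms 999 --seed 1

# statistics
microbeta stats anosim --dm dm_emd.tsv --meta sim/metadata.tsv --group order_group
microbeta stats enrich --fite fite.tsv --tax sim/taxonomy.tsv --top 10

# full pipeline from a config file
microbeta pipeline run --config study.yaml
```

A minimal `study.yaml`:

```yaml
outdir: out/
seed: 1
simulate: {}          # or table_path/taxonomy_path/tree_path/metadata_path
rarefaction_depth: 5000
min_otu_total: 10
metrics: [emd, wunifrac]
n_perm: 999
```

## Notes on the EMD construction

The histogram encoding assigns each nonzero OTU to one of B bins (default
69, or the nonzero-OTU count if smaller). Phyla are ordered by abundance and
given contiguous bin blocks sized proportionally to their OTU counts; block
anchor colors sit at greedily farthest-separated corners of the RGB cube,
the white corner is reserved (background carries no mass), and within-block
bins scatter in a small ball around the anchor so intra-phylum transport is
always cheaper than cross-phylum transport. The transportation problem is
solved exactly with HiGHS; a uniform ground distance (EMD degenerates to
total variation) is available as a sanity oracle.
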