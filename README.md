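# goiseek

Cell-type-specific gene association networks and seed-driven prioritisation
of pathway-responsive genes ("genes of interest") from microarray compendia.

The package implements four analysis stages plus a synthetic-data module
that makes every stage testable offline:

- **preprocess** — expression-call filtering from per-gene/per-array call
  scores in [0, 1] (a gene is expressed when some score strictly exceeds
  0.5), a missingness filter (drop genes missing in strictly more than half
  the columns), and row-wise KNN imputation.
- **network** — score-filtering of STRING-style link files (combined score
  ≥ 700 by default), restriction of the network to expressed genes, and a
  topology summary (nodes, edges, components, mean local clustering, degree
  assortativity).
- **bicluster** — seed-gene biclustering: arrays are greedily removed while
  the seeds' mean pairwise correlation is below a threshold (default 0.75,
  at most half the arrays), then pool genes are greedily added whenever they
  strictly increase the list's mean pairwise correlation; the two phases
  alternate to a fixed point.
- **deca** — differential-expression correlation ranking: per seed, the
  comparison set is reduced to where the seed is significant (p < 0.01);
  every gene gets a correlation vs the seed and a significance fraction;
  genes exceeding 0.6 on either (any seed) are ranked twice per seed (2n
  ranks) and ordered by the geometric mean rank.
- **assess** — in silico pathway-recovery protocol: random eligible seed
  triples per pathway (eligibility: significant in ≥ 15 comparisons),
  top-10% recovery fraction and a one-sided Welch t-test on final ranks,
  repeated 10 times with a seeded RNG.
- **simulate** — planted-bicluster expression matrices, planted-target DE
  matrices and random scored edge lists, each with truth labels and fully
  deterministic given an RNG seed.

## CLI

All functionality is exposed through a single entry point with six
subcommands; `--help` on any of them lists flags. A YAML config file may
provide one flat section per subcommand; command-line flags override it.
Every run writes a JSON log with the resolved configuration and input
checksums.

```sh
# generate a synthetic DE matrix with 3 seeds and 20 planted targets
goiseek simulate deca --n-genes 1000 --n-comparisons 80 --rng-seed 7 --out-dir sim/

# rank candidate genes against the seed genes
goiseek deca --de sim/de.tsv --pvalues sim/pvalues.tsv \
    --seeds G00123,G00456,G00789 --threshold 0.6 --out ranking.tsv

# build a cell-specific network from a STRING-style link file
goiseek network --links links.txt --score-min 700 \
    --expressed expressed.txt --out-edgelist net.tsv --out-summary topo.json

# run a seed-gene bicluster against a gene pool (GMT)
goiseek bicluster --matrix expression.tsv --seeds SQSTM1,HMOX1 \
    --pool pool.gmt --c-threshold 0.75 --out bicluster.json

# pathway-recovery assessment
goiseek assess --de sim/de.tsv --pvalues sim/pvalues.tsv \
    --pathways pathways.gmt --runs 10 --rng-seed 1 --out assessment.tsv
```

Matrix files are TSV with gene ids in the first column and array/comparison
ids in the first row; empty cells and `NA` are missing. Edge lists are
written as `gene_a<TAB>gene_b<TAB>` with an empty weight column.

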