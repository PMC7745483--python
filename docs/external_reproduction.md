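# Reproducing the full-scale evaluation on public data

The package's tests and benchmarks run on synthetic planted-structure data.
The full-scale protocol on the public databases is documented here; it
requires downloads whose contents drift over time, so its numbers are not
asserted anywhere in the test suite.

## Data

1. **Interactions** — lncRNA-miRNA interaction catalogue from lncRNASNP
   (http://bioinfo.life.hust.edu.cn/lncRNASNP). Export the experimentally
   verified interaction list as a two-column TSV `lncrna_id<TAB>mirna_id`.
   Duplicates are collapsed at load time.
2. **lncRNA sequences** — NONCODE (http://www.noncode.org), FASTA. Keep only
   lncRNAs present in the interaction list; ids must match the TSV.
3. **miRNA sequences** — miRBase (http://www.mirbase.org), mature miRNA
   FASTA, same id-matching rule.

After intersecting the three sources the reference compilation had 3784
interactions between 642 lncRNAs and 275 miRNAs; current database versions
will differ.

## Protocol

Full-scale reference settings: 5-spectrum features, LNS similarity, top-10
neighbor graphs, embedding dimension 120 for all five methods (GraRep
k-step 1; DeepWalk walk length 80, 30 walks per vertex, window 30; GAE
variational with hidden size 512), GEEL-PI with default Random Forests and
L2 logistic stacking, GEEL-FI with views {GraRep, LE}, pair dimension 160,
DANN hidden layers {240, 120}, 2000-tree forest. 5-fold cross-validation
over the full pair grid, repeated 20 times:

```bash
geel evaluate \
  --lncrna-fasta lncrna.fasta --mirna-fasta mirna.fasta \
  --interactions interactions.tsv \
  --head geel-fi --outdir results/full \
  --config full_scale.yaml
```

with `full_scale.yaml`:

```yaml
scale: full
n_components: 120
head: geel-fi
views: [GraRep, LE]
pair_dim: 160
n_estimators_fi: 2000
n_folds: 5
repeats: 20
seed: 0
```

Run `--head geel-pi` for the prediction-integration ensemble and the
`sparsity` subcommand for the robustness grid (removal ratios 0.1-0.4).

## What to expect

On a compilation of this size and density, ensemble AUPR in the ballpark of
0.65-0.70 and AUC above 0.9 are plausible; exact values depend on the
database versions and are not reproducible bit-for-bit. Expect hours of
runtime on one CPU (the 20-repeat CV dominates; the DeepWalk corpus and the
2000-tree forests are the heaviest single steps).
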