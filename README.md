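# driverank

Kernel one-class-SVM prioritization of candidate cancer driver genes.

Given a gold standard of known oncogenes (OG) or tumor suppressor genes
(TSG), driverank scores every other gene by its weighted similarity to the
known drivers, where the weights are fitted by a one-class SVM on a
precomputed kernel. Gene similarity can come from

- **mutation features** — per-gene 3-vectors built from a somatic-mutation
  table (damaging/total missense counts + positional entropy for OG;
  frameshift/LOF/splice-site counts for TSG),
- **a PPI network** — the diffusion kernel `exp(-L)` of the normalized graph
  Laplacian,
- or their average (**integrated kernel**).

A multitask extension ranks genes per cancer type by multiplying the gene
kernel with a disease kernel over (gene, disease) pairs; disease similarity
can be uniform, Dirac, their average, or based on 43-bit binary descriptors
(12 tumor-type + 31 localization characteristics).

Evaluation uses the consistency error `CE = #N × (1 − AUC)` — the mean
number of non-driver genes ranked above held-out known drivers — in a
repeated k-fold cross-validation protocol with an inner 5-fold grid search
over the regularization parameter `C ∈ {2^(−5/2), …, 2^(5/2)}`.

A fully seeded synthetic-data module generates mutation tables, PPI
networks with planted driver modules, and multi-disease driver structure so
the entire pipeline is testable offline.

## Library overview

| module | contents |
| --- | --- |
| `driverank.io_formats` | MAF-dialect mutation TSV, PPI edge lists, gene/pair lists, ranking TSVs |
| `driverank.mutation_features` | OG / TSG per-gene feature vectors, positional entropy |
| `driverank.kernels` | mutation / diffusion / degree / integrated kernels, degree-binned shuffling |
| `driverank.multitask` | disease descriptors, disease kernels, gene–disease pair kernel |
| `driverank.ocsvm` | one-class-SVM dual (capped-simplex QP), scoring, rankings |
| `driverank.evaluation` | CE/AUC, cross-validation, C tuning, per-disease regimes, diagnostics |
| `driverank.synthetic_data` | seeded generator with planted OG/TSG drivers and driver modules |
| `driverank.cli` | `driverank` command-line interface |

```python
from driverank import SyntheticConfig, generate, CVConfig, cross_validate
from driverank.evaluation import build_gene_kernel

table, net, truth, descriptors = generate(SyntheticConfig(seed=1))
K = build_gene_kernel(table, net, mode="TSG", choice="mutation+ppi")
result = cross_validate(truth.all_tsg(), K, table.gene_universe,
                        CVConfig(k=5, repeats=2, seed=1))
print(result.mean_ce)
```

## Command line

Subcommands: `features`, `kernel`, `rank`, `cv`, `disease-cv`, `simulate`,
`shuffle-benchmark`, `degree-diagnostic`. Every run writes its artifacts
plus a `run_metadata.json` (config echo, seed, versions, wall clock) to
`--outdir`; identical config + seed reproduces identical outputs.

```bash
driverank simulate --n-genes 200 --n-drivers 15 --seed 1 --outdir out/sim
driverank rank --mutations out/sim/mutations.tsv --ppi out/sim/ppi.tsv \
    --gold out/sim/truth_tsg.txt --kernel-choice mutation+ppi --outdir out/rank
driverank cv --mutations out/sim/mutations.tsv --ppi out/sim/ppi.tsv \
    --gold out/sim/truth_tsg.txt --k 5 --repeats 2 --seed 1 --outdir out/cv
driverank disease-cv --mutations out/sim/mutations.tsv --ppi out/sim/ppi.tsv \
    --pairs out/sim/truth_tsg_pairs.tsv --descriptors out/sim/descriptors.csv \
    --variant all --outdir out/dcv
```

## File formats

- mutation TSV: columns `Hugo_Symbol`, `Tumor_Sample_Barcode`, `Disease`
  (optional), `Variant_Classification`, `Protein_position`, `PolyPhen2`
- PPI edge list: two whitespace-separated gene symbols per line, `#` comments
- gene lists: one symbol per line; pair lists: `gene<TAB>disease`
- descriptor CSV: `disease` column + the 43 named binary columns
- rankings: `rank<TAB>gene<TAB>score`
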