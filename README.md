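# evcargo

Count-level analysis of small-RNA cargo in extracellular vesicles (EVs)
released by paired drug-sensitive / multidrug-resistant (MDR) tumor cells.

Tumor cells that overexpress drug-efflux pumps such as P-glycoprotein shed
EVs whose RNA cargo may disseminate the MDR phenotype. Given feature-by-sample
read-count matrices from such a study — two tumor models (NSCLC and CML), two
compartments (cells and their EVs), two phenotypes (drug-sensitive and MDR),
three replicates each — this package answers the questions that design poses:

* **Which RNA species change with MDR?** TMM-normalized counts-per-million
  filtering (CPM ≥ 2) followed by the conditional negative-binomial exact
  test per contrast, with Benjamini–Hochberg adjustment. For two groups of
  NB counts with common dispersion φ and equalized library sizes, the law of
  one group's sum *y*<sub>A</sub> given the total *t* is negative
  hypergeometric, and the two-sided p-value sums the probabilities of all
  splits no more likely than the observed one; at φ = 0 this is the exact
  binomial test.
* **Is EV loading proportional or selective?** Counts are summed over
  replicates per compartment, converted to reads per million (RPM) and
  log2-transformed; species detected in both compartments are regressed
  (EV on cell) and a linear grid search over noise thresholds *T* ∈
  {0, 0.1, …, 10} on the log2 RPM scale finds *T*<sub>max</sub>, the
  threshold maximizing R². A maximal R² that stays below 0.8 at every
  threshold indicates selective packaging.
* **Which changes replicate across tumor models?** Four-contrast Venn
  partitioning and a directional consensus table: species with p < α in both
  models and the same sign of log2 fold change (positive = up in MDR).
* **Does the data behave?** Biotype read-composition profiles, hierarchical
  clustering of significant features (1 − Pearson, average linkage), and
  classical-scaling ordination with the leading-fold-change distance —
  replicates should be mutual nearest neighbors.
* **Does qPCR agree?** Relative quantification by 2^−ΔΔCt against a stable
  reference miR, and sign-concordance with the sequencing fold changes.

Because studies of this kind rarely deposit raw data, the package ships a
first-class synthetic-data generator (`evcargo.simulate`) that emulates the
design with known truth — planted MDR effects partly shared across models,
log-normal packaging factors, abundance-dependent EV dropout, a realistic
biotype mix — so every stage is testable end to end.

## Worked example

```sh
evcargo simulate --out-dir demo --seed 1
evcargo selectivity --counts demo/counts.tsv --metadata demo/metadata.tsv \
    --model NSCLC --phenotype sensitive --out-dir demo
```

which logs (abridged):

```
selectivity NSCLC/sensitive: R2(0)=0.704, Tmax=2.2, R2(Tmax)=0.705 (consistent with selective packaging)
```

Read: at a zero noise threshold the EV-vs-cell log2 RPM regression explains
70% of the variance; the best threshold on the grid (2.2) barely improves it,
and since no threshold reaches R² = 0.8 the cargo is flagged as selectively
packaged — by construction, since the generator's default configuration gives
30% of species log-normal packaging factors. The same `demo` directory feeds
the other subcommands (`de`, `consensus`, `composition`, `cluster`, `qpcr`).

The same analysis from Python:

```python
import evcargo as ev

matrix, annotation, truth = ev.generate_dataset(ev.SimConfig(rng_seed=1))
pairs = ev.build_pairs(matrix.subset("NSCLC", "cell", "sensitive"),
                       matrix.subset("NSCLC", "EV", "sensitive"))
result = ev.grid_search_threshold(pairs)        # 0..10 in steps of 0.1
print(result.t_max, result.r_squared_at_tmax)   # 2.2 0.705
```

## Layout

| module                | role |
|-----------------------|------|
| `evcargo.core`        | data model (CountMatrix, annotation, config), TSV I/O, validation |
| `evcargo.simulate`    | synthetic study generator with planted truth |
| `evcargo.diffexpr`    | CPM filter, TMM, common dispersion, NB exact test, BH |
| `evcargo.selectivity` | RPM pairing, regression, threshold grid search |
| `evcargo.consensus`   | Venn partition, cross-model consensus, composition, target join |
| `evcargo.cluster`     | hierarchical clustering, leading-fold-change ordination |
| `evcargo.qpcr`        | 2^−ΔΔCt fold changes and NGS concordance |
| `evcargo.cli`         | `evcargo` subcommands over the above |

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
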