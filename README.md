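# mitolocus

Comparison machinery for mitochondrial species-identification loci
(cytochrome *b*, COI): per-site conservation profiling, a pairwise
distance suite, K2P-threshold species discrimination with full
contingency/ROC statistics, and tree-vs-taxonomy congruence scoring —
exercised end to end on synthetic data with known truth.

## Who this is for

Molecular ecologists and forensic geneticists evaluating a barcoding
locus face the same recurring questions: how conserved is the gene and
where; how large are intra- vs interspecific divergences; does a
"barcoding gap" exist and which distance threshold exploits it with
what error rates; and how well does a tree built from the locus recover
the accepted taxonomy. This package implements that entire evaluation
as a tested, reusable library plus a set of narrative analysis scripts.

## The statistics at its core

- **Conservation**: per-site `R_s = 2 − H` bits, with `H` the Shannon
  uncertainty of base frequencies; heteroplasmic (IUPAC-ambiguous)
  symbols count in the denominator but toward no base. Sliding-window
  identity `Σ R_s / 2X` for windows of X = 101, 401, 601 bp.
- **Distances**: p-distance; Kimura 2-parameter
  `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)` with saturation flagging; per
  codon-position partitions; Nei–Gojobori dS/dN under the vertebrate
  mitochondrial code; bootstrap standard errors (1,000 column
  resamples).
- **Discrimination**: same/different-species labelling with subspecies
  collapsing; 2×2 contingency tables at K2P (×100) thresholds
  1.5/2.0/2.5 with false positive/negative rates, sensitivity,
  specificity, PPV, NPV; barcoding-gap scan; ROC with Mann–Whitney AUC
  and Hanley–McNeil SE.
- **Phylogeny**: Neighbor-Joining (Saitou–Nei, deterministic
  tie-breaking) and congruence percentages per taxonomic rank via
  largest-pure-bipartition scoring, in per-sample and
  species-collapsed variants.
- **Synthetic data**: ranked taxonomies, ultrametric species trees, and
  K2P-evolved alignments with codon-position rate heterogeneity and
  rare heteroplasmy — with the ground truth returned alongside.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
from mitolocus import distances, discrimination, phylogeny
from mitolocus.synthetic_data import SimulationConfig, simulate_locus

config = SimulationConfig(seq_length=1500, inter_depth=0.08,
                          intra_depth=0.003, seed=11)
bundle, alignment = simulate_locus(config)          # 48 samples, 24 species
clean, _ = distances.complete_deletion(alignment)
k2p = distances.pairwise_matrix(clean, "k2p", scale_x100=True)
pairs = discrimination.label_pairs(k2p, bundle.taxonomy)

gap = discrimination.gap_scan(pairs)
print(gap.max_intra, gap.min_inter)    # 0.4685776068357355 6.39987842889019
m = discrimination.metrics(discrimination.contingency(pairs, 1.5))
print(m.fp_rate, m.fn_rate)            # 0.0 0.0
print(discrimination.roc(pairs).auc)   # 1.0

tree = phylogeny.nj_tree(distances.pairwise_matrix(clean, "k2p"))
report = phylogeny.congruence(tree, bundle.taxonomy, "order")
print(report.overall_percent)          # 100.0
```

The largest within-species K2P (×100) is 0.47 and the smallest
between-species value 6.40 — an empty interval (the barcoding gap), so
every threshold inside it separates species perfectly: zero false
positive and false negative rates at 1.5, AUC 1.0, and the NJ tree
groups every order of the generating taxonomy correctly (100%).

## Analysis scripts

The numbered drivers under `analysis/` run the full two-locus study on
simulated data and write tables under `results/`:

```
python analysis/01_simulate.py        # two loci + taxonomy + true trees
python analysis/02_conservation.py    # R_s tracks, windows, variable sites
python analysis/03_distances.py       # p/K2P/dS/dN matrices + bootstrap SEs
python analysis/04_discrimination.py  # gap, thresholds, ROC
python analysis/05_congruence.py      # NJ trees + congruence per rank
python analysis/06_locus_report.py    # consolidated side-by-side report
```

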