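# motudelim

Single-locus DNA-barcode species delimitation and partition agreement
scoring, built for the question every barcoding study of a diverse
assemblage faces: **how well do molecular operational taxonomic units
(MOTUs) recover morphologically defined species, and where do they
fail?**

Given an aligned barcode matrix (e.g. 658-bp cox1 for a few hundred
specimens), a specimen→morphospecies table, and optionally a
phylogenetic tree, the package:

* computes pairwise distances under p, JC69 and K80 (K2P) with pairwise
  deletion, plus infra/interspecific summaries and the barcode-gap
  histogram;
* delimits MOTUs six ways — 3% K2P threshold clustering (single
  linkage), ABGD barcode-gap discovery with its recursive prior scan,
  TCS statistical parsimony at the 95% connection limit, and the
  Poisson tree processes PTP (exact ML), bPTP-style MCMC support, and
  multi-rate mPTP — and can score externally supplied partitions (e.g.
  BIN assignments) the same way;
* scores any MOTU partition against the reference morphospecies with
  the match ratio

      match ratio = 2 · N_match / (N_MOTU + N_morph)

  where N_match counts groups whose specimen sets are identical in both
  partitions, plus per-species agreement classes
  (match / split / lumped / mixed) and a monophyly report;
* simulates calibrated synthetic assemblages (Yule species tree,
  within-species coalescents, deep-coalescence and haplotype-sharing
  knobs, K80 sequence evolution) with known truth labels, so every
  method is testable end to end without downloads.

See `docs/methods.md` for the models and numerical choices.

## Worked example

Simulate an assemblage that mirrors a densely sampled single-locality
beetle fauna (56 species, 14 singletons, ~190 specimens, 12 species
with deep intraspecific splits), then run the whole comparison:

```bash
python analysis/01_simulate_assemblage.py
python analysis/02_distance_summary.py
python analysis/03_delimit_all_methods.py
python analysis/04_regime_comparison.py
```

`02` prints the distance structure of the default assemblage:

```
infraspecific: mean 0.0179, median 0.0123, max 0.0836
interspecific: mean 0.1773, min 0.0248
species with max infraspecific K2P > 3%: 12; species pairs with min interspecific < 3%: 1
```

— the classic picture: infraspecific distances near 1–2% with a tail of
deep-coalescence species reaching ~8%, against interspecific distances
centred near 17%, so the "barcode gap" is real but leaky.

`04` contrasts a clean regime (no deep splits, shallow within-species
variation) with a hard one (half the species deeply split):

```
method     easy_n_motu  easy_ratio  deep_n_motu  deep_ratio
threshold  56           1.00        83           0.39
abgd       56           1.00        143          0.14
tcs        56           1.00        104          0.26
ptp        56           1.00        146          0.14
bptp       56           1.00        146          0.14
mptp       55           0.97        75           0.49
```

On cleanly separated species every method recovers the truth (the
multi-rate model lumps one sister pair — its exact optimum, see
`docs/methods.md`).  Deep coalescence drives heavy oversplitting and
the match ratios collapse, which is exactly the failure mode reported
for real single-locus assemblages.

The same machinery is scriptable:

```python
import motudelim as m

aln, truth = m.simulate_assemblage(m.SimulationConfig(), seed=42)
dm = m.pairwise_distances(aln, "k80")
motus = m.threshold_cluster(dm, 0.03)
report = m.compare_partitions(motus, truth.labels.to_partition())
print(report.n_match, report.n_motu, report.ratio_2dp)
```

and a `delimit` CLI wraps the pipeline
(`delimit simulate`, `delimit cluster`, `delimit tree`,
`delimit compare`, `delimit run`).

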