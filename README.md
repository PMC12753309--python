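# sedabench

Benchmarking postprocessing workflows for **sedimentary ancient DNA
(sedaDNA)** community data.

DNA preserved in lake and marine sediments records past communities, and
transfer functions calibrated on modern community–environment pairs can
turn those records into paleoenvironmental reconstructions. But ancient
DNA is degraded: many taxa that were present go undetected (false
negatives), alpha diversity drops, and relative abundance profiles skew.
`sedabench` provides a tested pipeline to ask which analysis choices
survive that noise:

1. **Simulate** structured community count matrices (100 samples × 400
   taxa by default) with either discrete community types (5 clusters) or
   a continuous ecological gradient, via a negative-binomial hierarchy
   with per-run parameters drawn from uniform ranges. Synthetic per-taxon
   sequences and a coalescent phylogeny make sequence- and tree-aware
   methods testable without downloads.
2. **Degrade** each matrix into an "ancient" version: a quarter of
   samples at each dropout level e ∈ {0, 25, 50, 75 %}, where a fraction
   e (± small jitter) of a sample's detected taxa is zeroed and the
   removed reads are reallocated to a random subset of that sample's
   top-decile taxa — sequencing depth is preserved exactly.
3. **Benchmark** a grid of 13 count transformations (prop, rarefy,
   Hellinger, chi-square, CSS, clr, rclr, VST, TMM, TMMwsp, wrench, GMPR,
   k-mer) × 16 beta-diversity indices (Euclidean, Bray–Curtis, Canberra,
   Kulczynski, Morisita–Horn, Gower, alt-Gower, Chao, Pearson, Spearman,
   RF proximity, TINA, PINA, weighted/generalized/variance-adjusted
   UniFrac) × 4 ordinations (PCoA, NMDS, t-SNE, UMAP), scoring each
   combination by the PERMANOVA pseudo-F

   F = (SS_model / df_model) / (SS_resid / df_resid)

   computed from the Gower-centred matrix of −d²/2 (McArdle–Anderson),
   on both the dissimilarity matrix itself and on Euclidean distances
   between the 2-D ordination coordinates, plus the betadispersion F.
4. **Evaluate transfer functions**: KNN and random-forest models trained
   on the modern samples only (60–40 split, repeated 10-fold CV for
   tuning) and applied to the degraded samples, reporting transfer
   accuracy (clusters) or RMSE on the min-max-normalized gradient, per
   effect level, with Tukey-HSD comparison of the top approaches.

## Worked example

```python
import sedabench as sb

params = sb.draw_sim_params(seed=1, mode="cluster",
                            overrides={"n_samples": 50, "n_taxa": 200})
modern = sb.simulate_community(params)
plan = sb.assign_effect_levels(modern.metadata, mode="cluster", seed=1)
ancient, realized = sb.degrade_matrix(modern, plan)

for name, ds in [("modern", modern), ("ancient", ancient)]:
    dm = sb.compute_distance(ds, "hellinger", "bray", seed=1)
    f, p = sb.permanova_f(dm, ds.metadata.to_numpy(), n_perm=999, seed=1)
    emb = sb.ordinate(dm, sb.OrdinationOptions(method="umap", seed=1))
    fe, pe = sb.permanova_f(sb.embedding_distance(emb),
                            ds.metadata.to_numpy(), n_perm=999, seed=1)
    print(f"{name}: distance-level F = {f:.1f} (p = {p:.3f}); "
          f"UMAP embedding F = {fe:.1f} (p = {pe:.3f})")

config = sb.MLConfig(algorithm="knn", feature_space="embedding", seed=1)
record = sb.transfer_evaluate(modern, ancient,
                              sb.GridCombo("hellinger", "bray", "umap"),
                              config, plan=realized)
print("transfer accuracy by effect level:",
      {k: round(v, 3) for k, v in record.transfer_by_level.items()})
```

prints

```
modern: distance-level F = 9.8 (p = 0.001); UMAP embedding F = 8192.7 (p = 0.001)
ancient: distance-level F = 2.3 (p = 0.001); UMAP embedding F = 34.0 (p = 0.001)
transfer accuracy by effect level: {0.0: 1.0, 0.25: 1.0, 0.5: 1.0, 0.75: 0.9}
```

Degradation cuts the Hellinger/Bray–Curtis pseudo-F from 9.8 to 2.3 — the
cluster signal is still there but much weaker — while the same distance
matrix pushed through a UMAP embedding keeps the clusters crisply
separated (F = 34 on the degraded data), and a KNN transfer function
calibrated on the modern coordinates still assigns 90 % of the samples
that lost 75 % of their detected taxa to the correct cluster. The
p-values are permutation p-values (999 free permutations).

## Command line

Each stage is also a subcommand of the `sedabench` CLI and writes a small
replay manifest next to its outputs:

```bash
sedabench simulate --mode cluster --n-samples 100 --n-taxa 400 --seed 1 --out-dir ds
sedabench degrade ds/counts.tsv ds/metadata.tsv --mode cluster --seed 1 --out-dir ancient
sedabench transform ds/counts.tsv --method hellinger --out hell.tsv
sedabench distance hell.tsv --index bray --out bray.tsv
sedabench ordinate bray.tsv --method umap --seed 1 --out emb.tsv
sedabench benchmark config.yaml --out results.csv
sedabench preprocess counts.tsv metadata.tsv --out-dir prepped
```

Counts and metadata are plain TSV (samples in rows), sequences FASTA,
trees Newick.

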