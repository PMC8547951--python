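# kairoscan

Detection and validation of **bivalent chromatin** — the co-localization of an
activating and a repressive histone modification on the same genes — over
**metabolic gene sets**, built for the *Arabidopsis*-style setting where binned
epigenomic signal profiles are integrated with a PlantCyc/PMN-style
gene → pathway → domain annotation.

The package is aimed at regulatory genomicists who have (a) gene models
(GFF3), (b) binned, per-mark genome signal tracks (bedGraph), (c) a metabolic
annotation table (TSV), and (d) qPCR Cq / metabolite concentration tables
(CSV) from follow-up experiments, and who want the whole chain — signal
densities, enrichment calls, bivalency statistics, and the ChIP-qPCR /
sequential-ChIP / expression-kinetics arithmetic — as tested, scriptable
pieces. A seeded synthetic-data generator with planted ground truth makes
every stage testable without any external download.

## The statistics at the core

**Signal density.** Each track is rank-normalized per mark
(value → fractional rank in (0, 1]). Each gene contributes a strand-aware
window: transcribed region plus 1 kb upstream and 500 bp downstream. For a
gene set *S* with windows *w(g)*,

    density(S, mark) = Σ_{g∈S} signal(w(g)) / Σ_{g∈S} |w(g)|

where bins overlapping a window contribute proportionally to the overlap.
The **background** is the same density over all metabolic genes.

**Enrichment.** For each set × mark, the effect size is the fold change
FC = density / background; significance is Fisher's exact test on
marked-gene counts (a gene is *marked* when its density reaches the 0.75
quantile of the universe, configurable), BH-FDR-adjusted over the whole
set × mark family. A set is *enriched* when FC ≥ 1.5 and q ≤ 0.01
(depleted symmetrically at FC ≤ 1/1.5); a raw-p gate (p < 0.05) is
available as a flag.

**Bivalency.** Two signatures: co-occurrence (fraction of the universe
marked by both modifications) and correlation attribution (Pearson *r* of
per-gene densities between the marks, with p from t = r·√((n−2)/(1−r²)),
recomputed after removing a candidate subset — a drop in *r* attributes the
correlation to that subset).

**qPCR arithmetic.** Percent input 100·2^((Cq_input − log2(1/f)) − Cq_IP);
relative abundance = treated/mock percent input; sequential-ChIP percent of
first ChIP 100·2^(Cq_2nd − Cq_1st) (with a sign-corrected variant); ΔΔCq
fold change 2^−ΔΔCq with pooled-variance t-tests; earliest-induction calls;
balanced three-way factorial ANOVA (genotype × treatment × duration) with
Type I sums of squares.

## Worked example

```python
import kairoscan as ks
from kairoscan.bivalency import correlation_attribution, dual_enriched_sets
from kairoscan.signal_density import build_windows

cfg = ks.SimConfig(seed=1)          # 1000 genes, 2 marks, planted effects
ds = ks.simulate_all(cfg)

tracks = [ks.rank_normalize(t) for t in ds.tracks]
signals = ks.compute_gene_signals(build_windows(ds.annotation), tracks)

sets = ks.filter_pathways(ds.metabolic, min_genes=10, domain="specialized")
results = ks.call_enrichment(signals, sets, ds.annotation.gene_ids)
for r in results:
    if r.set_id == "PWY-CAMALEXIN":
        print(f"{r.set_id} {r.mark_name}: FC={r.fold_change:.2f} "
              f"q={r.q_value:.1e} -> {r.direction}")

dual = dual_enriched_sets([r for r in results if r.mark_name == "H3K27me3"],
                          [r for r in results if r.mark_name == "H3K18ac"])
print("dual-enriched pathways:", dual)

subset = frozenset(g for g in ds.annotation.gene_ids
                   if ds.metabolic.unique_domain(g) == "specialized")
full, wo = correlation_attribution(signals, "H3K27me3", "H3K18ac",
                                   ds.annotation.gene_ids, subset)
print(f"Pearson r: {full.pearson_r:.2f} -> {wo.pearson_r:.2f} "
      "after removing specialized genes")

fc = ks.ddcq_fold_change(ds.cq, "CYP71A13", "ACT2", "Col-0", 30)
print(f"CYP71A13 (Col-0, 30 min): FC={fc.fold_change:.2f}, p={fc.p_value:.1e}")
```

prints

```
PWY-CAMALEXIN H3K18ac: FC=1.64 q=1.8e-12 -> enriched
PWY-CAMALEXIN H3K27me3: FC=1.61 q=1.8e-12 -> enriched
dual-enriched pathways: ['PWY-BIVALENT', 'PWY-CAMALEXIN', 'PWY-GLUCOSINOLATE']
Pearson r: 0.60 -> 0.00 after removing specialized genes
CYP71A13 (Col-0, 30 min): FC=4.89, p=9.4e-09
```

The planted camalexin-like pathway (signal multiplier 3 on both marks) is
called enriched for the repressive and the activating mark simultaneously;
the cross-mark correlation over all metabolic genes collapses once the
co-elevated specialized genes are removed — the bivalency signature; and the
ΔΔCq machinery recovers the planted ~4-fold induction of *CYP71A13* at
30 min of elicitor treatment.

The same chain is available from the shell:

```
kairoscan pipeline --seed 1 --out run/
kairoscan simulate  --config sim.yaml --out data/
kairoscan density   --gff data/genome.gff3 --tracks data/*.bedgraph --out densities.tsv
kairoscan enrich    --densities densities.tsv --pathways data/pathways.tsv \
                    --level pathway --out enrichment.tsv
```

Every pipeline run writes a `manifest.json` (tool version, config hash,
seed, record counts); identical config + seed reproduces a byte-identical
output set.

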