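# midgutlam

Linearized, region-aware analysis of segmented *Drosophila* midgut nuclei.

The adult fly midgut is a curved tube divided into anatomically recognizable
regions (R1–R5, delimited by borders B1–B4) whose size and cell-type
composition adapt to nutrition. Microscopy pipelines segment its nuclei in
3D and export object tables — centroid, maximum cross-sectional nucleus
area, mean marker intensities — but organ-wide, region-resolved questions
("where along the gut do enteroblasts accumulate after refeeding?") need
those point clouds mapped onto a common one-dimensional axis. `midgutlam`
does that end to end for cohorts of midguts:

1. **Axis linearization** — fit a piecewise median polyline (the "vector")
   through the xy point cloud, project every object onto it, and bin the
   normalized position `u = s/L` into `n_bins` segments
   (`AxisLinearizer`, a scikit-learn style transformer).
2. **Regional profiles** — per-bin tracks: total and per-type counts,
   polyploid ("large") nucleus area via a bimodal log-area ploidy gate,
   3D nearest-neighbor distances among large nuclei, and midgut width
   (2 × median radial offset).
3. **Border detection** — a multivariate border score: weighted sum of
   z-scored windowed deviations `|mean(b−w, b] − mean(b, b+w]|` of width,
   large-nucleus area, nearest distance and counts; borders = the k
   highest peaks under non-maximum suppression (`BorderDetector`), plus
   region lengths and border-based cross-sample alignment.
4. **Cell classification** — marker positive/negative gates
   (histogram-valley or quantile), FUCCI cell-cycle phases from the two
   reporter states (E2F1⁺CycB⁻ = G1, E2F1⁻CycB⁺ = S, both = G2-M), and
   progenitor doublet pairing (mutual nearest neighbors with cluster
   exclusion) with symmetry classes: Delta⁺/Delta⁺ symmetric ISC–ISC,
   Delta⁺/Delta⁻ asymmetric ISC–EB, Delta⁺Prospero⁺ → ISC–preEE.
5. **Statistics** — bin-wise two-sided Wilcoxon rank-sum tests (exact by
   enumeration for combined n ≤ 10, tie-corrected normal approximation
   with continuity otherwise) under Benjamini-Hochberg FDR across bins;
   Kruskal-Wallis with pairwise follow-up; paired t; two-factor ANOVA with
   Tukey HSD.
6. **Synthetic midguts** — a seeded generator producing nucleus tables of
   a curved five-region tube with region-specific radii, polyploid/diploid
   area bimodality, cell-type composition, marker intensity models, and
   fed-vs-starved effects (radius × 1.6; region-specific ISC-area,
   EB-count and EE-count folds), with full per-record ground truth for
   parameter-recovery testing.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from midgutlam import (SynthConfig, generate_cohort, analyze_sample,
                       BorderDetector, per_bin_compare)

cfg = SynthConfig()                      # default five-region midgut
cohort = generate_cohort(cfg, n_per_group=8, seed=42)

profiles = {cond: [analyze_sample(tab, type_col="true_type")[2]
                   for tab, _ in samples]
            for cond, samples in cohort.items()}

det = BorderDetector().fit(profiles["starved"])
print("borders (bins):", det.borders_.bins)

ws = np.vstack([p.table["width"] for p in profiles["starved"]])
wf = np.vstack([p.table["width"] for p in profiles["fed"]])
ok = ~np.isnan(ws).all(0) & ~np.isnan(wf).all(0)
fold = np.mean(np.nanmean(wf, 0)[ok] / np.nanmean(ws, 0)[ok])
print(f"fed/starved width fold: {fold:.2f}")

res = per_bin_compare(profiles["starved"], profiles["fed"], feature="width")
print("significant width bins:", int(res["significant"].sum()))
```

Output:

```
borders (bins): [19 44 54 84]
fed/starved width fold: 1.54
significant width bins: 92
```

The four called borders sit at the generator's true region boundaries
(u = 0.20, 0.45, 0.55, 0.85 → bins 19/44/54/84). The measured width fold
1.54 recovers the injected 1.6× fed radial scale (the median-offset width
estimator carries a small condition-independent downward bias that cancels
almost entirely in the ratio), and with an organ-wide radius change nearly
every bin away from the noisy organ termini is significant at FDR 0.05.

## Command line

Each stage is also a subcommand over CSV/JSON/YAML files:

```bash
midgutlam simulate --n-per-group 8 --seed 42 --out sim/
midgutlam linearize --in sim/starved_0.csv --slices 30 --bins 100 --out proj.csv
midgutlam profile --in proj.csv --type-col true_type --out profile.csv
midgutlam borders --profiles profiles.csv --k 4 --window 5 --out borders.json
midgutlam doublets --in sim/starved_0.csv --radius 10 --out doublets.csv
midgutlam phases --in sim/starved_0.csv --out phases.csv
midgutlam compare --group-a starved.csv --group-b fed.csv --feature large_area --out stats.csv
midgutlam pipeline --seed 42 --out run/
```

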