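# embryoquant

Per-nucleus immunofluorescence quantification in 3D for mouse blastocyst
confocal stacks.

Peri-implantation mouse embryos — in particular diapaused blastocysts, whose
implantation is experimentally delayed — are densely packed balls of cells in
which the levels of pluripotency markers (phosphorylated STAT3 pY705,
TFCP2L1, NANOG) must be measured nucleus by nucleus to compare embryonic
stages. `embryoquant` is a reusable implementation of the image-cytometry
workflow this requires, aimed at developmental biologists quantifying
confocal IF of preimplantation embryos:

1. **Segmentation by z-linking.** Nuclei are detected independently on each
   2-µm optical section of the DNA channel (unsharp mask → 1–99.9 percentile
   contrast normalisation → threshold at 0.2 → distance-transform watershed
   splitting → IoU overlap suppression → per-slice area filter, 5 < A < 30 µm²),
   then linked through z by greedy nearest-neighbour matching of centroids.
   Chains spanning more than 5 sections become 3D nuclei.
2. **Quantification.** Each 3D label masks every channel of the raw stack:
   centroid (x, y, z in µm), voxel count, volume V = n·Δx·Δy·Δz, per-channel
   mean intensity, and **integrated density** — the sum of all voxel values
   in the object, `intden_c = mean_c × n_voxels`. QC windows on the DNA mean
   (2, 10) and volume (150, 700) µm³ remove mis-segmented objects, and an
   optional region-of-interest mask restricts analysis to the embryonic
   region (excluding mural trophectoderm).
3. **Statistics.** The marker distributions are heavy-tailed and bimodal, so
   comparisons are rank-based: pairwise two-sided Wilcoxon rank-sum tests
   (exact enumeration for small samples, tie-corrected normal approximation
   otherwise), Kruskal–Wallis H across stages, with Brown–Forsythe and
   Shapiro–Wilk diagnostics and the usual star labels
   (ns p>0.05; \* p≤0.05; \*\* p≤0.01; \*\*\* p≤0.001; \*\*\*\* p≤0.0001).
4. **In-silico embryos.** Nuclei become points in a co-expression space
   (e.g. NANOG vs pY705 integrated density); threshold or polygon gates
   select subpopulations, which are mapped back into 3D reconstructions of
   their embryo of origin and summarised per embryo (cell counts, mean
   marker level, spatial enrichment, size–intensity association).
5. **Synthetic embryos.** A ground-truthed generator renders blastocyst-like
   8-bit z-stacks (ICM cluster inside a trophectoderm shell, lineage- and
   stage-specific lognormal marker intensities, shot + read noise) so every
   stage of the pipeline is testable without microscope data.

## Worked example

```python
import pandas as pd
from embryoquant import (SyntheticEmbryoSpec, render_stack, segment_stack,
                        measure_nuclei, qc_filter, apply_region,
                        embryonic_roi, make_cohort, compare_stages)

# one diapaused embryo: render, segment, measure
spec = SyntheticEmbryoSpec(stage="diapause", seed=3)
stack, truth = render_stack(spec)
labels, tracks = segment_stack(stack)
table = qc_filter(measure_nuclei(labels, stack, embryo_id="demo",
                                 stage="diapause"))
print(f"planted {len(truth)} nuclei, segmented {len(tracks)}, "
      f"{len(table)} pass QC")

# a small three-stage cohort and the stage comparison on pY705
cohort = make_cohort(3, SyntheticEmbryoSpec(), seed=11)
tables = []
for e in cohort:
    lab, _ = segment_stack(e.stack)
    t = measure_nuclei(lab, e.stack, embryo_id=e.embryo_id, stage=e.stage)
    t = apply_region(t, embryonic_roi(e.spec), e.stack.calibration)
    tables.append(qc_filter(t))
results, summary = compare_stages(pd.concat(tables, ignore_index=True), "pY705")
for r in results:
    if r.test in ("wilcoxon", "kruskal_wallis"):
        print(f"{r.test:>15} {' vs '.join(r.groups):<28} "
              f"p={r.p_value:.3g}  {r.label}")
```

prints

```
planted 30 nuclei, segmented 30, 30 pass QC
       wilcoxon E3.5 vs E4.5                 p=0.03  *
       wilcoxon E3.5 vs diapause             p=0.223  ns
       wilcoxon E4.5 vs diapause             p=0.0248  *
 kruskal_wallis E3.5 vs E4.5 vs diapause     p=0.0277  *
```

All 30 planted nuclei are recovered and pass QC; pY705 in the embryonic
region is significantly higher in diapause than at E4.5 even in this small
cohort (nine embryos), while E3.5 and diapause are not separable at this n.

The same pipeline is scriptable from the shell:

```sh
embryoquant simulate --n-per-stage 3 --seed 11 --out sim/
embryoquant run-all --manifest sim/manifest.csv --out run/
```

which writes per-embryo label TIFFs and nucleus tables, `stats.csv`,
violin-ready per-stage summaries, gate selections and a machine-readable
run log.

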