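# spherotype

Machine-learning quantification of 3D spheroid invasion phenotypes from
time-lapse microscopy.

Multicellular spheroids embedded in extracellular-matrix gel are imaged
hourly (one phase-contrast field per well, typically 72 h). Some
genotypes or treatments drive spheroids from a compact **Spherical**
morphology to a **Hyper-protrusive** one — radial protrusions invading
the surrounding matrix. `spherotype` turns such image stacks into
per-condition, per-time-chunk phenotype frequencies with
replicate-aware statistics, for cell biologists running invasion
assays or image-based CRISPR screens on this readout.

The pipeline:

1. **simulate** – a seeded synthetic-data generator (growing spheroids,
   protrusive morphology class, focus-loss runs, drift, full
   condition × biological replicate × well hierarchy) with ground truth,
   standing in for non-public instrument data;
2. **segment** – Otsu segmentation plus greedy nearest-centroid
   tracking;
3. **features** – shape, size, brightness, Haralick texture,
   granularity-spectrum and movement measurements per object and frame;
4. **train / classify** – two Fast Gentle Boosting stump classifiers
   (focus QC, then phenotype), exported as plain-text rules files that
   classify new datasets prospectively without retraining;
5. **stats** – 6-h time chunks, control z-scores, log₂ fold changes,
   Cochran–Mantel–Haenszel tests stratified by biological replicate,
   Breslow–Day homogeneity of odds ratios, Bonferroni adjustment, and
   bubble-heatmap-ready tables.

## The statistics in brief

For condition vs control in chunk *t*, counts of Hyper-protrusive vs
Spherical objects form a 2×2×K table over the K biological replicates.
The CMH statistic

> χ²_CMH = [Σ_k (a_k − E_k)]² / Σ_k V_k,  E_k = r_k s_k / T_k

(1 df, no continuity correction) is significant only when the effect is
consistent across replicates. Effect-size reproducibility is tested
with the Breslow–Day statistic around the Mantel–Haenszel common odds
ratio ψ̂ (K−1 df, no Tarone correction): a non-significant result is
the "black dot" marking a homogeneous effect. Both families are
Bonferroni-adjusted over conditions × chunks. The boosting classifier
fits one regression stump per round by weighted least squares with
±1 class coding and multiplicative weight updates; its rules
`IF (feature > θ, [scores if true], [scores otherwise])` are the entire
model.

## Worked example

The built-in demo config (two conditions, `p_hyper` 0.1 vs 0.7, 3
biological replicates × 2 wells, 24 hourly frames, seed 7):

```sh
spherotype all --outdir demo_run --seed 7
```

writes images, `observations.csv`, `features.csv`, rules files,
`labelled.csv`, `counts.csv`, `stats.csv` and `heatmap.png` under
`demo_run/`, and prints:

```
condition        phenotype  chunk_start  chunk_end   p_ctrl  z_ctrl   log2fc  cmh_stat    p_raw    p_adj  psi_mh  bd_stat     bd_p  bd_p_adj homogeneous
 invasive Hyper-protrusive            1          6 0.083333    -0.5 3.169925 20.645161 0.000006 0.000022    26.6 1.964682 0.374433  1.000000        True
 invasive Hyper-protrusive            7         12 0.083333    -0.5 3.169925 20.645161 0.000006 0.000022    26.6 1.964682 0.374433  1.000000        True
 invasive Hyper-protrusive           13         18 0.083333    -0.5 3.169925 20.645161 0.000006 0.000022    26.6 1.964682 0.374433  1.000000        True
 invasive Hyper-protrusive           19         24 0.125000     1.5 2.584963 17.857143 0.000024 0.000095    16.0 3.411766 0.181612  0.726448        True
```

Reading the first row: in hours 1–6 the control shows a Hyper-protrusive
proportion of 0.083 (z −0.5 across chunks); the invasive condition is
2^3.17 ≈ 9× enriched; the CMH test is significant after Bonferroni
(p_adj 2.2e-5) with a Mantel–Haenszel odds ratio of 26.6; and the
Breslow–Day test is non-significant (p_adj 1.0), i.e. the effect
magnitude is homogeneous across the three replicates — this cell would
be drawn as a large red bubble with a black dot.

Classify a new feature table with existing rules, no training data
needed:

```sh
spherotype classify --outdir new_run \
    --rules-focus demo_run/rules_focus.txt \
    --rules-phenotype demo_run/rules_phenotype.txt
```

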