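# imccn

Spatial analysis of imaging mass cytometry (IMC) data for tumor-
microenvironment studies, together with the exact endpoint statistics of a
single-arm phase II trial design.

IMC images a tissue section with a panel of metal-tagged antibodies, giving
one ion-count intensity plane per marker. Turning those planes into
statements about the microenvironment — which cell phenotypes are present,
how they organize into recurrent local structures such as tertiary lymphoid
structures (TLS) or vascular zones, and which cell types engage or avoid
each other — takes a pipeline of well-defined stages. `imccn` implements
that pipeline end to end and ships a ground-truthed synthetic-data generator
so every stage is testable without any patient data:

1. **preprocess** — channel-spillover compensation (per-pixel unmixing
   `o = t·S` against a spillover matrix `S`), 3×3 median filtering, and
   linear rescaling of each plane to the full 0–255 range;
2. **segment** — nucleus thresholding (Otsu or fixed), connected-component
   labeling (4/8-connectivity), and membrane assignment: each
   membrane-positive fragment joins the nearest nucleus center, and
   fragments more than 15 px from every center are discarded as artifacts;
3. **quantify** — per-cell mean intensities, normalized per channel to the
   99th percentile (clipped at 1);
4. **phenotype** — PhenoGraph-style clustering: a k-nearest-neighbor graph
   (k = 100) with Jaccard shared-neighbor weights, partitioned by Leiden
   modularity communities;
5. **neighborhoods** — cellular neighborhoods (CNs): each cell's window is
   itself plus its 20 nearest cells; windows are summarized as cell-type
   composition vectors and K-means-clustered (k = 15) into microenvironment
   motifs, with a clipped Voronoi map for visual validation;
6. **interactions** — permutation interaction/avoidance tests (phenotype
   labels shuffled within image, positions fixed, p-values with the +1
   correction) and patient-level CN × cell-type count tensors;
7. **endpoints** — Clopper-Pearson exact binomial intervals for ORR/DCR,
   Kaplan-Meier survival (median = earliest t with S(t) ≤ 0.5), the
   one-proportion normal-approximation sample size
   `n = ⌈(z₁₋α/₂√(p₀q₀) + z_pow√(p₁q₁))²/(p₁−p₀)²⌉`, and dropout inflation
   `⌈n/(1−d)⌉`.

## Worked example

```python
import numpy as np
from imccn import (NicheSpec, SegmentationConfig, assign_neighborhoods,
                   clopper_pearson, default_panel, extract_features,
                   generate_tissue, normalize_p99, one_prop_sample_size,
                   permutation_test, phenotype_cells, render_image,
                   segment_cells)

# 1. simulate a 600-cell tissue: a TLS-like aggregate of two lymphocyte-like
#    types on a parenchyma of three other types, imaged with counting noise
niches = [
    NicheSpec("tls", 0.35, (0.5, 0.5, 0, 0, 0), "aggregate",
              n_foci=2, focus_sd=80.0),
    NicheSpec("parenchyma", 0.65, (0, 0, 0.4, 0.4, 0.2)),
]
tissue = generate_tissue(600, 5, niches, field_size=(800, 800), seed=11)
panel = default_panel(5)
image, truth_mask = render_image(tissue, panel, seed=11)

# 2. segment and quantify
mask = segment_cells(image, SegmentationConfig("DNA", ("Membrane",), min_area=5))
cells = normalize_p99(extract_features(image, mask), panel.channels)
print(f"segmented {mask.n_cells} cells (planted {tissue.n_cells})")

# 3. phenotype clusters and cellular neighborhoods
pheno = phenotype_cells(cells, panel.channels, k=100, seed=7)
cells["phenotype"] = pheno.labels
cells, cn_model = assign_neighborhoods(cells, w=20, k=2, seed=7)
print(f"{pheno.n_clusters} phenotype clusters, {cn_model.k} neighborhoods")

# 4. do the two aggregated phenotypes co-locate more than chance?
a = int(pheno.cluster_means["Lin0"].idxmax())
b = int(pheno.cluster_means["Lin1"].idxmax())
res = permutation_test(cells, radius=30.0, n_perm=999, seed=3)
print(f"Lin0+ cluster {a} vs Lin1+ cluster {b}: "
      f"enrichment p = {res.p_enrich[a, b]:.3f}")

# 5. trial endpoints from the published response counts (18/36 responders)
ci = clopper_pearson(18, 36, 0.95)
print(f"ORR {100*ci.estimate:.1f}% (95% CI {100*ci.lower:.1f}-{100*ci.upper:.1f}%)")
print(f"required sample size: {one_prop_sample_size(0.278, 0.50)}")
```

Output:

```
segmented 604 cells (planted 600)
5 phenotype clusters, 2 neighborhoods
Lin0+ cluster 2 vs Lin1+ cluster 3: enrichment p = 0.001
ORR 50.0% (95% CI 32.9-67.1%)
required sample size: 35
```

The segmenter recovers the planted cells (a few extra labels come from
noise specks and touching membranes at this noise level), the five planted
phenotypes come back as five clusters, the two tissue compartments as two
CNs, and the planted co-aggregation of the two lymphocyte-like phenotypes
is detected as a significant pairwise enrichment. The endpoint block
reproduces the trial's published ORR interval and design sample size from
its input counts.

A thin CLI mirrors the stages (`imccn simulate`, `imccn preprocess`,
`imccn segment`, `imccn quantify`, `imccn phenotype`,
`imccn neighborhoods`, `imccn interactions`, `imccn endpoints`,
`imccn simulate-trial`); run `imccn --help` for the file formats.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions and known limitations.
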