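# tamspatial

Spatial analysis of tumor-associated macrophage (TAM) populations from
multiplex immunohistochemistry (m-IHC) cell tables.

Multiplexed staining panels (here: CD68, CD163, CD206, IRF8, PDL1 and the
pan-cytokeratin cocktail AE1AE3) let a supervised image-analysis system
export one row per segmented cell — nucleus coordinates, tissue compartment
(tumor-nest vs stroma), region of interest (tumor core / edge / margin /
adjacent normal) and per-marker mean intensities. `tamspatial` takes that
table and answers the questions a tumor-immunology group asks of it:

* **Who is each cell?** A fixed-priority intensity gate assigns every cell
  to Tumor (AE1AE3+), one of seven macrophage populations — two M1-like
  (CD68+IRF8+, CD68+) and five M2-like (CD68+CD163+, CD68++CD163+,
  CD68+CD206+, CD68+CD206++, CD68+CD163+CD206+) — or Other. "++" denotes a
  second, higher intensity threshold.
* **Where are they?** Per-patient density tables by ROI and compartment
  with the M1:M2 ratio; nearest-cell distance statistics: for each
  reference cell (RC) the Euclidean nucleus-to-nucleus distance to the
  nearest cell (NC) of a target phenotype, summarized as per-patient
  medians, the *effective percentage* (fraction of RCs with an NC inside
  each 10 µm distance bin) and the *effective density* (RCs with an NC
  within the 10 µm direct-contact radius, per mm² of tissue).
* **How do markers change at the tumor border?** Signed distances to the
  tumor-nest/stroma interface (positive into the nest), compartment-balanced
  sampling, binned mean-intensity profiles with confidence bands, and a
  threshold-based quadrant classification of each side.
* **What does the microenvironment look like?** PDL1 positivity against the
  mean of size-balanced subsampling cohorts (equal cells per patient);
  patient-level PDL1-high calls from top-percentile macrophages;
  *environmental gene signatures* — genes whose whole-tissue expression
  correlates (Spearman) with a population's density across patients, with
  BH-FDR and a refined p < 0.001 tier; Kaplan–Meier / log-rank (Mantel–Cox)
  survival stratification by density terciles or signature median splits.
* **Is the phenotyping robust?** Subsample-stability of marker signatures
  (Pearson), and a k-means sweep over the number of populations.

Because real m-IHC cohorts cannot ship with a package, `tamspatial`
includes a first-class synthetic cohort generator
(`tamspatial.simulate`) that produces seeded patient cohorts — clustered
tumor-nest geometry, population-specific placement relative to tumor cells,
per-phenotype intensity mixtures, interface gradients, density-linked
expression and density-driven survival — with full ground truth, so every
analysis step is testable against known structure. See
`docs/methods.md` for the model details.

## Worked example

```python
import numpy as np
import tamspatial as ts

cfg = ts.SimulationConfig(n_patients=8, seed=1)
data = ts.generate_cohort(cfg)

cells = data.cells.copy()
cells["phenotype"] = ts.classify_cells(cells, cfg.true_gating())
print("gating accuracy:", (cells["phenotype"] == cells["true_phenotype"]).mean())

core = cells[cells["roi"] == "core"]
for pop in ("CD68+IRF8+", "CD68++CD163+", "CD68+CD163+CD206+"):
    d = ts.nearest_distances_by_image(core, pop, "Tumor")
    print(pop, round(ts.median_distance(d["distance_um"]), 1), "um")

dens = ts.density_table(cells, data.image_areas)
rec, dused = ts.generate_survival(dens, cfg)
terc = ts.tercile_stratify(dused)
curves, chi2, p = ts.km_logrank(rec, terc, ("upper", "lower"))
print(f"log-rank upper vs lower tercile: chi2={chi2:.3f}, p={p:.4f}")
```

Output:

```
gating accuracy: 0.9939
CD68+IRF8+ 10.6 um
CD68++CD163+ 13.3 um
CD68+CD163+CD206+ 23.5 um
log-rank upper vs lower tercile: chi2=0.076, p=0.7822
```

The gate recovers 99.4% of the generating labels; the IRF8+ macrophages
(generated proximal to tumor cells) show a much shorter median
nucleus-to-nucleus distance than the distal triple-positive population; and
with only 8 patients the density-tercile survival comparison is, as it
should be, far from significance.

## Command line

The `tamspatial` entry point chains the pipeline stages
(`simulate → phenotype → density → distance → gradient → pdl1 → signature
→ survive`); each subcommand runs up to and including its stage, `all`
runs everything:

```sh
tamspatial all --seed 7 --out runs/demo          # synthetic end-to-end
tamspatial density --config study.yaml --out runs/real
```

Every output directory contains tidy CSV artifacts plus a `manifest.json`
recording the seed, a configuration hash and the SHA-256 of each artifact;
two runs with the same configuration and seed are byte-identical.

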