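# ovamat

Computational toolkit for mapping the ovarian extracellular matrix
(**matrisome**) during early follicular development. The package bundles the
analysis stages such a study needs — Raman hyperspectral unmixing, AFM
surface/stiffness map statistics, rule-based follicle staging with a puberty
score, and matrisome omics categorization — together with synthetic-data
generators that give every stage a known ground truth, so the whole pipeline
is testable without instrument data.

**Who it is for.** Reproductive-biology and biomechanics groups that acquire
Raman maps and AFM force maps of ovarian (or other soft) tissue and want a
transparent, scriptable alternative to instrument-vendor black boxes; and
anyone who needs the bookkeeping around matrisome gene lists, DEG filtering
and mRNA–protein concordance done reproducibly.

## What it computes

**Raman unmixing.** A hyperspectral map is an n-channels × m-pixels matrix
A. After a fixed preprocessing chain — truncation to 400–2000 cm⁻¹, cosmic
spike removal against the 3×3 spatial-neighborhood median, SNIP baseline
subtraction, 9-point Savitzky–Golay smoothing, per-pixel area normalization
— A is factorized as

    A ≈ W · S,      W ≥ 0 (n × k pure-component spectra),
                    S ≥ 0 (k × m concentration profiles),

by minimizing ‖A − W·S‖²_F with multiplicative updates, multiple seeded
restarts, unit-area W columns, and components sorted by total abundance.
Rows of S reshape to per-component abundance images (collagen, GAG, cell
contrast).

**AFM maps.** Surface roughness of a height map (Z_i, i = 1…N):

    Sa_rms = sqrt( (1/N) Σ (Z_i − Z_avg)² ),
    Sa_mean_abs = (1/N) Σ |Z_i − Z_avg|   (ISO variant),

plus masked-aware Young's-modulus summaries and profile extraction.

**Follicle metrics.** Histological staging (primordial / primary /
secondary / antral, with exclusion when the oocyte nucleus is not visible),
MVH/ZP3 immunofluorescence count arithmetic, and the puberty score: the
diameter class of the largest healthy antral follicle maps to an ordinal
score — SF (<250 µm) → −5, F1 (250–300) → −4, F2 (300–350] → −3,
F3 (350–400] → −2, F4 (>400) → −1.

**Matrisome omics.** Categorization of gene/protein lists against a
MatrisomeDB-style reference (collagens, proteoglycans, glycoproteins, ECM
regulators, ECM-affiliated, secreted factors, or non-matrisome),
cross-species Venn region algebra, the strict DEG criterion
|log2FC| > 1 and p < 0.05, and nine-quadrant mRNA–protein concordance with
Pearson correlation.

## Worked example

```python
from ovamat.synthetic import default_raman_phantom, gen_raman_cube
from ovamat.raman import PreprocessConfig, RamanUnmixingModel
from ovamat.raman.annotate import load_reference_peaks

spec = default_raman_phantom(grid_shape=(40, 30), seed=1)
cube, truth, spikes = gen_raman_cube(spec)

model = RamanUnmixingModel(cube, preprocess=PreprocessConfig())
res = model.fit(k=3, n_restarts=10, seed=42)
print(res.summary())
```

```
Raman NMF unmixing results
==========================================
components (k)      : 3
channels x pixels   : 801 x 1200  (grid 40 x 30)
restarts            : 10   seed: 42
iterations (best)   : 201
final objective     : 0.0193905
relative error      : 0.1411
------------------------------------------
component  total abundance  peak (cm^-1)
        0            436.2        1668.0
        1            385.1        1062.0
        2            362.8        1004.0
```

The three components recovered from the noisy phantom peak at 1668, 1062 and
1004 cm⁻¹ — amide I (collagen-like), the GAG C–O/sulfate band, and the
phenylalanine cell-body marker. Matching detected peaks against the bundled
literature table labels them automatically:

```python
refs = load_reference_peaks()
for i in range(res.k):
    print(i, res.annotate(i, refs).assigned_label)
# 0 collagen
# 1 GAG
# 2 unassigned   (cell-body component: not in the ECM reference table)
```

The relative error (0.14) sits at the phantom's noise-plus-residual floor;
`res.abundance_maps()` returns the three (30, 40) concentration images, and
`res.plot_abundances("maps.png")` renders them.

A follicle cohort runs the same way:

```python
from ovamat.synthetic import CohortSpec, gen_follicle_cohort
from ovamat.follicle import tally_stages, puberty_score

cohort = gen_follicle_cohort(CohortSpec(n_follicles=200, seed=4))
print(tally_stages(cohort.records))
# {'primordial': 117, 'primary': 30, 'secondary': 37, 'antral': 16,
#  'excluded': 0, 'total': 200}
res = puberty_score(cohort.records)
print(res.top_class, res.score)   # F4 -1  (largest healthy antral 444.6 µm)
```

Every stage is also exposed on the command line (`ovamat --help`):

```bash
ovamat simulate raman --seed 7 --out cube.h5
ovamat raman preprocess --in cube.h5 --out pre.h5
ovamat raman unmix --in pre.h5 -k 3 --restarts 10 --seed 42 --out comps.h5
ovamat afm roughness --in height.tsv --variant rms
ovamat follicle pubscore --in cohort.csv
ovamat matrisome quadrant --in omics.csv
```

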