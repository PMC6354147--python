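# sectmorph

**How much does the choice of section plane change 2D morphometry?**

In biomaterial research, healing of grafted bone (e.g. socket-preservation
sites treated with particulate hydroxyapatite) is conventionally quantified
by histomorphometry: percent area of mineralized bone, residual graft, and
noncalcified tissue measured on a single stained section. Micro-CT provides
the same specimen as a 3D volume, from which a virtual section can be taken
at *any* plane. That freedom exposes a problem with the 2D gold standard: if
a small parallel offset or rotation of the section plane substantially
changes the percent areas, then any single-section measurement is a fragile
summary of the specimen.

`sectmorph` is an in-silico replica of that sensitivity experiment:

1. **Phantoms** — synthetic three-phase microstructures (correlated trabecular
   bone field, hard-sphere graft particles, noncalcified background) rendered
   to grayscale with noise and blur, plus a "histology proxy" reference
   section with label-flip noise.
2. **Geometry** — oriented section planes with parallel offsets in whole
   pixels along the normal (±4 px × 19.75 µm = ±79 µm) and ±10° rotations
   about the in-plane vertical axis, and trilinear/nearest section extraction
   with out-of-volume masking.
3. **Segmentation** — per-image two-threshold (three-class) Otsu with
   optional manual override maps.
4. **Morphometry** — percent areas over a centered 4 × 4 mm ROI, and
   phase-wise overlap (concordance area rate: Jaccard/Dice).
5. **Plane matching** — coarse-grid + Nelder–Mead search for the virtual
   section most similar (mean per-phase Dice) to a 2D reference.
6. **Agreement** — Lin's concordance correlation coefficient

   ρ_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²),

   with z-transform 95% CI, mean difference ± SD, Bland–Altman limits of
   agreement, and Pearson/ICC comparators.
7. **Study pipeline** — a 16-specimen cohort, six measurements per specimen
   (reference proxy + matched plane + 4 perturbed planes), and the two
   agreement blocks per phase, fully reproducible from one master seed.

## Worked example

```python
from sectmorph import PhantomSpec, StudyConfig, run_study

config = StudyConfig(n_specimens=16,
                     phantom=PhantomSpec(shape=(64, 64, 64)),
                     master_seed=1)
report = run_study(config)
block = report.table_bone.query("block == 'vs_hm'")
print(block[["comparison", "ccc", "mean_diff", "sd_diff"]].round(3).to_string(index=False))
```

prints (reference-proxy comparison block, percent bone area):

```
 comparison   ccc  mean_diff  sd_diff
   original 0.916     -2.904    1.193
   offset+4 0.734     -2.057    5.589
   offset-4 0.705     -2.376    5.105
rotation+10 0.593     -7.579    3.663
rotation-10 0.568     -6.966    4.284
```

Read: the virtual section *matched* to the reference agrees strongly
(CCC 0.92, small scatter of differences), while every section taken only
79 µm away or rotated by 10° agrees far worse (CCC 0.57–0.73, with 3–5×
the difference SD) — the section plane itself is a major source of
variance in 2D morphometry. The small negative bias (≈ −2.9) is the
systematic offset between label-level truth and threshold segmentation of
a blurred rendering, shared by all five virtual sections.

A CLI mirrors the modules: `sectmorph simulate | reslice | segment |
measure | match | agree | run-study` (see `sectmorph --help`).

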