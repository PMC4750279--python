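# fdlung

Fractal-dimension radiomics of chest CT attenuation patterns.

Conventional radiomics of lung CT either summarises the attenuation
histogram (which ignores spatial structure) or computes fractal dimensions
of pre-segmented anatomy (vessels, airways). `fdlung` implements a third
approach designed for *non-gated* (micro-)CT of the chest: the attenuation
scale is divided into contiguous **cut-off ranges**, the lung voxels of each
range form a 3D binary pattern, each pattern receives a **box-counting
fractal dimension**, and the resulting **fractal-dimension–cut-off-range
function** is decomposed into two Gaussian components whose parameters — and
their A/B ratios — discriminate exposure groups. Because the data are not
respiration-gated, motion-blended attenuation patterns are part of the
signal rather than an artefact.

The package is aimed at preclinical imaging groups analysing mouse chest
scans (and at anyone who wants a well-tested 3D box-counting estimator).
Since no reference scans are publicly deposited, a phantom module generates
(a) deterministic fractal sets with known dimension for estimator
validation and (b) chest-like attenuation volumes whose FD curves follow
prescribed two-Gaussian profiles, up to full multi-group cohorts.

## The method

For a masked volume and cut-off ranges `[l_i, h_i)` (by default 100 ranges
of 130 relative HU spanning −3000…+10000):

1. **Binarise**: voxel → 1 if its attenuation lies in range *i*, else 0.
2. **Box counting**: for box side `s`, `NB(s)` is the number of grid boxes
   holding at least one occupied voxel; two grid placements (anchored at 0
   and shifted by half a box) are averaged into `E(NB)(s)`.
3. **Power law**: OLS of `log E(NB)` on `log s` gives
   `fd_i = max(0, −slope)`, clipped to the embedding dimension 3; empty
   patterns get exactly 0.
4. **Two-Gaussian fit**:
   `fd(x) ≈ h_A e^{−(x−p_A)²/2w_A²} + h_B e^{−(x−p_B)²/2w_B²}`,
   component A being the lower-position peak. Heights are in fd units,
   positions/widths in relative HU (width = Gaussian σ).
5. **Group statistics**: Kruskal–Wallis across groups plus pairwise
   Mann–Whitney post hoc tests (exact at small n) on each parameter and on
   the A/B ratios `h_A/h_B`, `p_A/p_B`, `w_A/w_B`.

## Worked example

`examples/03_fd_curve_and_two_gaussian_fit.py` builds a 64³ attenuation
phantom targeting the control-group curve, analyses it end to end and
prints (abridged):

```
parameter      recovered      target
height_a             2.2         2.3
position_a         706.7       735.0
width_a           1067.5      1086.0
height_b             1.3         1.3
position_b        3684.8      3776.0
width_b           1645.3      1562.0

A/B ratios: height 1.743, position 0.192, width 0.649
```

The recovered parameters match the generator's targets to within a few
percent, and the height ratio sits near the control-scale value
2.291/1.276 ≈ 1.80. `examples/04_cohort_comparison.py` simulates the
three-arm exposure design (n = 5/5/6, groups differing only in the height
of component B) and prints the Kruskal–Wallis/Mann–Whitney report; the
sulphur-dioxide-like arm separates from both others on `height_b` and the
height ratio (exact MW p = 0.004–0.008) while position parameters stay
non-significant.

The other examples validate the estimator on known-dimension fractals
(line/plane/cube/Menger sponge: fd 1.0000 / 2.0000 / 3.0000 / 2.7268) and
demonstrate lung segmentation plus the attenuation-histogram fit.

## Command line

```bash
fdlung phantom --kind attenuation --size 64 --seed 7 --out vol.nii.gz
fdlung segment  --in chest.nii.gz --out mask.nii.gz --threshold -300
fdlung fdcurve  --in chest.nii.gz --mask mask.nii.gz --out curve.tsv
fdlung fit      --curve curve.tsv --out fit.json
fdlung compare  --params cohort_params.tsv --out report.json
fdlung pipeline --in chest.nii.gz --outdir results/
```

Volumes are NIfTI, MetaImage or raw+JSON-sidecar; curves and parameter
tables are TSV, fits and reports JSON.

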