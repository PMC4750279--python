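# Methods

This note documents the models and procedures `fdlung` implements, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish about real data.

## The analysis chain

### Segmentation

Only the set of lung voxels matters downstream; the segmenter is therefore
deliberately simple and fully reproducible: voxels below an air/parenchyma
threshold (default −300 relative HU) are candidates; candidate components
connected to the volume border are ambient air and are removed; the largest
one or two remaining components (default minimum 100 voxels) are kept and
closed with a spherical element of radius 2 voxels. Interior holes —
vessels, bronchial walls — are *not* filled: the method analyses all
lung-voxel attenuations, dense structures included, so closing only smooths
the boundary. The thresholds are parameters, and an externally produced
mask can always be substituted; attenuation scales of cone-beam micro-CT
reconstructions are instrument-relative, so the default threshold should be
checked against each scanner's air/tissue contrast.

### Cut-off ranges and binarisation

The attenuation span (default −3000 to +10000 relative HU) is divided into
`n` equal, contiguous cut-off ranges (default 100, i.e. 130 relative HU per
range). Interior ranges are half-open `[low, high)` and the last range is
closed, so the binary patterns partition the in-span masked voxels exactly;
a boundary value belongs to the higher range. Masked voxels outside the
span belong to no pattern and trigger a logged warning, since with the
default span this should not occur. The Freedman–Diaconis rule
(`width = 2·IQR·n^(−1/3)`) is available as an alternative to the fixed
count; quartiles use the midpoint convention (for values 1…8 the IQR is 4),
which keeps the rule's arithmetic simple and documented.

### Box counting

For one binary pattern and box side `s`, `NB(s)` counts grid cells holding
at least one occupied voxel. Two placements are used: a grid anchored at
voxel index 0, and one shifted by half a box (anchor −⌊s/2⌋ per axis) —
one canonical alternative grid rather than all `s³−1` shifts, which keeps
`E(NB) = (NB_aligned + NB_offset)/2` a mean of two counts. Boxes clipped by
the volume boundary count when non-empty; discarding partial boxes biases
slopes on small volumes. Counting maps occupied-voxel coordinates to cell
indices and counts distinct cells — `O(n log n)` in occupied voxels and
exactly equal to a brute-force scan over all boxes (asserted against a
triple-loop oracle in the tests).

The fractal dimension is `max(0, −slope)` of the ordinary least-squares
line through `(log s, log count)` over sizes with count ≥ 1, clipped to the
embedding dimension 3. Degenerate curves — empty patterns, a single usable
size — give exactly 0, which is what puts the FD curve at zero in
attenuation ranges no lung voxel reaches. Default sizes are all integers
from 1 to min(100, half the grid edge); power-of-two or power-of-three
subsets are preferable when exact scaling matters, because ceiling effects
at non-divisor sizes flatten the fitted slope (a solid 64³ cube fits 3.000
on divisor sizes, 2.898 on sizes 1…16, and only 2.759 on sizes 1…32 — all
values from the `⌈N/s⌉³` closed form, which the estimator reproduces
exactly).

### Two-Gaussian decomposition

The FD–cut-off-range function is fitted with
`h_A·exp(−(x−p_A)²/2w_A²) + h_B·exp(−(x−p_B)²/2w_B²)` by bounded
nonlinear least squares (scipy `curve_fit`, trust-region reflective).
Initialisation is a fixed, deterministic set of seeds — two well-separated
smoothed local maxima; fd-mass quantile seeding; per-side moments after a
split at the weighted median — and the lowest-RSS solution wins, so the fit
is a pure function of the curve. Components are relabelled so A has the
lower position; "width" is the Gaussian σ throughout. Bounds keep the
optimiser in physical space: heights in [0, 3.5] (slightly above the
embedding dimension), positions within the curve's span, widths between one
range width and a third of the span. The width ceiling matters: with
unbounded widths the strongly overlapped decomposition is ill-conditioned
and component B occasionally absorbs tail noise as a near-flat background,
which destabilises the fitted heights; one third of the span still exceeds
every realistic component width by a comfortable margin. Fewer than 7
points with positive fd is an error (six free parameters plus one);
non-convergence of every start returns a flagged result rather than raising.

Goodness of fit uses a Pearson-type statistic
`Σ (obs − model)² / max(model, ε)` with `ε = 0.01` fd units, summed over
*all* curve points, dof = points − parameters. Flooring the denominator —
rather than excluding low-model points — keeps two failure modes visible:
structure the model misses entirely still inflates the statistic, while
tail noise contributes boundedly. Model selection fits both the one- and
two-component models and picks two components when the single Gaussian is
rejected at p < 0.05 and the two-component p-value is higher.

### Group statistics

Cohorts are compared per parameter (six fitted parameters plus the three
A/B ratios) with a Kruskal–Wallis test across all groups and pairwise
two-sided Mann–Whitney post hoc tests. scipy supplies the statistics and
asymptotic p-values (mid-ranks, tie corrections, continuity correction);
exact small-sample p-values are computed in-package by enumeration — the KW
permutation null for pooled n ≤ 12, and the tie-aware MW label enumeration
for sides ≤ 8 without ties (with ties the normal approximation is used in
auto mode, but exact mode handles ties correctly through mid-ranks). At the
reference design (n = 5/5/6) the pairwise tests are exact and the KW
p-value uses the chi-square reference, whose exact size at that design is
0.0419 at nominal 0.05.

No multiple-testing correction is applied by default — post hoc p-values
are reported raw alongside the KW p, mirroring the reporting style of the
exposure study this mirrors — and a Holm step-down option is available.
Each pairwise decision is reported both raw and gated on KW significance,
since the gating convention is ambiguous in the source analyses.

## Phantoms

### Estimator validation

Line, plane, solid cube and Menger sponge have closed-form box counts and
known dimensions (1, 2, 3, log20/log3 ≈ 2.7268); the sponge at power-of-3
aligned sizes is exact to 10⁻⁹ because the counts are exactly collinear in
log–log space. Random dust (iid Bernoulli occupancy) provides the
monotone-occupancy family used by `calibrate_occupancy`: nested dust
prefixes give a monotone occupancy→fd table with endpoints 0 and the
solid-region fd. These phantoms validate the estimator; they are not
chest-like.

### Attenuation phantoms

The generator produces volumes whose FD curve follows a prescribed
two-Gaussian profile, replacing the undeposited animal scans as test and
demonstration substrate. Realising a target fd in *every* cut-off range
simultaneously is a voxel-budget problem: patterns must be disjoint (a
voxel has one attenuation), and unstructured dust needs occupancy ≈ 0.3
per range to reach fd ≈ 2.5 at desk scale — summed over the ~40 active
ranges that is several times more voxels than the volume holds. Patterns
that are self-similar across the analysed box-size decade reach the same
fitted fd at a small fraction of the cost, so each range is realised as a
union of two random octree-cascade clusters: inside a 16³ region anchored
on the counting grid, each cell keeps a stratified random subset of its 8
children (mean branching `m`, never fewer than 1), giving dimension
≈ log2 m per octave. An empirical branching→fd table, built with the
package's own estimator on the same mask geometry, is inverted per range;
the cluster is deliberately overshot and then trimmed — random subsets,
bisected on the monotone subset-size→fd relation — to within ~0.03 of the
target, with trimmed voxels returned to the free pool. Targets below the
small-pattern granularity floor (~0.4, where a handful of voxels cannot
realise intermediate fd) are rounded to the nearer realisable value, which
keeps tail errors small and roughly zero-mean without injecting random
bumps. An optional second pass regenerates the volume with targets
corrected by the smoothed residual of a full analysis of the first pass.

Defaults: 64³ grid, 54 μm isotropic spacing (echoing the source geometry at
a desk-friendly size), ellipsoidal lung mask (semi-axes 0.45/0.40/0.42 of
the edge), box sizes (1, 2, 4, 8) with aligned placement — powers of two on
grid-aligned anchors keep cluster regions exactly tileable, raising the
estimator's finite-size ceiling to ≈ 2.9 so that reference-scale peaks
(≈ 2.5–2.75) remain realisable. Analyses of these phantoms should use the
same sizes and placement (`PhantomResult.box_sizes` / `.placement`).
Measured fidelity at these defaults, control-scale targets, two passes:
heights and widths recover within a few percent, positions within ~5% of
scale; the infeasibility guard rejects target curves whose expected voxel
demand exceeds twice the mask.

Cohorts draw per-subject target parameters from group-level normal
distributions (heights clipped to [0, 3], widths to ≥ 2 range widths,
positions into the span) with per-subject seeds derived from the cohort
seed; everything is bit-reproducible given the seed. The stored reference
parameter scales for the three exposure arms (sulphur dioxide, smoke+ozone,
control) have B-heights 1.725 / 1.376 / 1.276 — the discriminating feature
— with within-group SD 0.08 on the B-height in the reference power
scenario.

### What the phantoms do not show

The phantoms guarantee only the FD-curve signature, not anatomy: cluster
patterns are not airway trees, attenuation values are uniform within each
range rather than tissue-like, ranges occupy spatially coherent random
patches instead of interdigitating at alveolar scale, and respiratory
motion — which the non-gated method deliberately integrates — is not
modelled at all. Passing tests therefore establish that the *pipeline*
(binning → box counting → decomposition → statistics) measures what it
claims and discriminates curve-level group differences at the stated
sample sizes; they do not establish that real exposure models produce such
differences.

## Simulation sizes

Simulation problem sizes are chosen so the whole suite runs on a single
CPU in minutes while keeping each conclusion meaningful:

* parameter-recovery and discrimination-power simulations use 64³ phantoms
  (50 cohort replicates of n = 5/5/6 for power);
* the null (type-I) simulation uses 500 replicates of 32³ phantoms with 50
  cut-off ranges and halved curve heights — the rejection rate is invariant
  to these reductions because identically distributed groups remain
  exchangeable whatever the pipeline does to each subject, so the rate
  equals the KW test's size (0.0419 exactly at n = 5/5/6) regardless of
  volume scale;
* estimator-oracle equivalence is exhaustive over box sizes on ≤ 32³
  patterns.

## Known limitations

* Relative-HU scales are instrument-specific; nothing here calibrates
  against clinical Hounsfield units, and cross-device comparisons of
  positions/widths are not meaningful.
* The box-counting fd at desk-scale grids saturates below 3 for averaged
  placement and general size lists; comparisons should fix one size list
  and placement throughout a study.
* The two-Gaussian decomposition is ill-conditioned when components overlap
  strongly; with noisy curves the height split between A and B can flip
  even when the summed curve is well fit. The bounded fit and deterministic
  multi-start mitigate but cannot remove this.
* The segmenter is threshold-based; pathologies that raise parenchymal
  attenuation above the threshold would shrink the mask and should be
  handled with an external mask.
* DICOM series, cone-beam reconstruction, gating/motion modelling, lobe or
  vessel segmentation, lacunarity and multifractal spectra are out of
  scope.
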