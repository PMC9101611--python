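# Methods

## Problem and pipeline

Dermoscopy photographs of pigmented skin lesions — benign nevi (BN),
dysplastic nevi (DN) and melanomas (MM), imaged under polarized and
non-polarized light — are quantified by second-order texture statistics of
fixed-size regions of interest (ROIs) and compared across the three
histopathological groups.  The pipeline has four stages:

1. **Imaging I/O** — 8-bit grayscale conversion and extraction of square
   450 × 450-pixel ROIs at explicit offsets, with provenance (source image,
   lighting mode, lesion group) attached to every object.
2. **Preprocessing** — per-ROI intensity normalization to the μ ± 3σ
   window, then quantization to `Ng` gray levels.
3. **Texture features** — five statistics per ROI (below).
4. **Group statistics** — normality-routed omnibus tests with post-hoc
   pairwise orderings, reported per feature per lighting mode.

## Texture statistics

With `p(i, j)` the symmetric, normalized gray-level co-occurrence matrix
(GLCM) at a fixed pixel displacement, `p_{x−y}(m) = Σ_{|i−j|=m} p(i, j)`
its difference histogram, and `r(i, k)` the run-length matrix (RLM)
counting maximal runs of level `i` and length `k`:

- `Entropy  = −Σ_{i,j} p(i,j) log p(i,j)`
- `DifEntrp = −Σ_m p_{x−y}(m) log p_{x−y}(m)`
- `LngREmph = Σ_{i,k} k² r(i,k) / Σ_{i,k} r(i,k)`
- `TI = Entropy / LngREmph` (texture index)
- `BI = DifEntrp / LngREmph` (bone index)

`0 · log 0 := 0`; `LngREmph ≥ 1` with equality iff every run has length 1.
TI and BI measure structural diversity per unit of uniform longitudinal
structure; advanced melanomas — dominated by solid dark areas — drive
`LngREmph` up and both entropies down, so TI and BI drop steeply.

### Conventions

- **Displacement**: distance 5 in grid steps, four canonical offsets
  (0,5), (5,0), (5,5), (5,−5).  The diagonal offsets use Chebyshev
  distance, the convention of classic texture-analysis packages.
- **GLCM symmetry**: pairs are accumulated in both orders (Haralick
  convention), so `p(i,j) = p(j,i)` and the sign of the offset is
  irrelevant.
- **Run directions**: horizontal, vertical and both diagonals; runs are
  scanned per line, **without a run-length cap** (`Nr` = ROI side).
  Capping would silently truncate exactly the uniform-dark-area signal
  that separates melanoma.
- **Aggregation**: each feature is computed per direction and reduced by
  the arithmetic mean (configurable); TI and BI are formed from the
  aggregated values, per ROI.  Group statistics are taken over per-ROI
  values, never as ratios of group means.
- **Logarithm**: natural log by default; a different base rescales
  Entropy, DifEntrp, TI and BI by a constant and leaves every ordering
  unchanged (`log_base` flag).
- A constant ROI gives Entropy = DifEntrp = TI = BI = 0 and a horizontal
  `LngREmph` of side²; note the diagonal scan lines of a square are
  shorter than the side, so the 4-direction mean of `LngREmph` for a
  constant ROI is below side².  Closed-form checks therefore pin the
  horizontal direction.

## Preprocessing choices

`level(v) = clamp(1 + floor((v − (μ − 3σ)) / 6σ · Ng), 1, Ng)`, with μ, σ
the mean and **population** standard deviation over all ROI pixels
(whole-ROI density statistics, not sample estimates).  Values at or beyond
the window edges clamp to levels 1 / Ng.  A constant ROI (σ = 0) maps to
the mid level `round((Ng+1)/2)` so constant images stay constant.

- `Ng = 64` by default (any power of two 4–256).  Six-bit reduction is
  the convention of the texture-software family this analysis follows,
  and it keeps the GLCM well-populated at 450² pixels.
- Floor-based binning with ties going to the higher level; an explicit
  formula so every downstream number is reproducible.
- Because the window is defined in units of the ROI's own σ, the level
  array — and therefore every feature — is invariant under affine
  intensity rescalings `v → a·v + b` (a > 0), up to pixels landing
  exactly on a bin edge.  This is what makes features comparable across
  differently exposed photographs.
- Grayscale conversion of RGB inputs uses ITU-R BT.709 luminance weights
  (0.2126, 0.7152, 0.0722) with round-half-up, configurable to BT.601.
  Deterministic and documented, close to common editors' "luminosity"
  mode; bit-exact agreement with any particular GUI editor is not
  claimed.

## Statistical stage

Per feature and lighting mode, the three lesion groups are compared with:

1. Shapiro–Wilk normality per group (valid for 3 ≤ n ≤ 5000).
2. One-way ANOVA iff **every** group passes at α (the conservative
   reading of normality-dependent routing); otherwise Kruskal–Wallis.
3. When the omnibus p < α: Tukey HSD after ANOVA, Dunn's rank z-test with
   Bonferroni correction after Kruskal–Wallis (standard companions of
   each omnibus test; the method used is recorded in the report).  Dunn's
   test is implemented in-package (tie-corrected mean-rank differences);
   Tukey HSD comes from statsmodels.
4. Orderings: when all pairwise contrasts separate at α and the group
   centers are monotone, a total order is reported ("MM > DN > BN", most
   advanced lesion first); otherwise the significant pairs; otherwise
   "n.s.".

Two-group inputs (e.g. melanoma in situ vs invasive) route through the
same gate to Student's t / Mann–Whitney U.  Classic equal-variance ANOVA
is used (a Welch correction is deliberately not applied, matching the
plain one-way design); no correction is applied across the five features.

Calibration of the routed pipeline is verified by simulation: under the
null (three identical Gaussian groups, n = 30) the rejection rate over
1000 replicates stays within 3 binomial SDs of α = 0.05, and power rises
monotonically with group separation.

## Synthetic cohort

The study's lesion photographs are not redistributable, so a generator
produces 450 × 450 8-bit ROIs carrying the statistical structure the
analysis targets.  Per ROI: (1) white noise smoothed by a Gaussian kernel
of scale `correlation_length` (the quasi-regular pigment pattern),
rescaled to a mid-gray band (mean 150, SD 22); (2) uniformly dark
elliptical patches stamped at an absolute dark value below the eventual
μ − 3σ window edge, so they quantize to level 1 and generate long runs
(melanoma's "uniformly black areas"); (3) in non-polarized mode, contrast
compression of the subsurface field (× 0.55) plus additive specular glare
blobs, modelling surface reflection; (4) Gaussian pixel noise, clamp to
[0, 255].  Per-ROI lognormal jitter of the correlation length (and, in
non-polarized mode, of the noise level) supplies within-group
heterogeneity.  Seeding is hierarchical from a single base seed via
`SeedSequence(base, class, lighting, index)`, so any single image is
reproducible in isolation.

**Preset calibration.**  The per-class presets are calibration artifacts,
not biological measurements: they are fixed so that a 166-ROI-per-group
cohort reproduces the qualitative group patterns the analysis is built to
detect.  Under polarized light the classes differ in correlation length
(1.6 / 2.2 / 3.0 px) and dark-patch load (3 / 6 / 12 patches of growing
size and depth), which orders all five features.  Under non-polarized
light all classes share one correlation length and — crucially — the same
expected total dark area and the same window inflation (`area × depth²`);
only the *geometry* differs: BN and DN carry ~12 small globules, MM two
large structureless blotches.  Equalizing the window inflation pins both
entropies together across groups (they stay non-significant at n = 166)
while the blotch geometry still drives `LngREmph` — and hence TI and BI —
far apart, reproducing the reported loss of entropy contrast without
cross-polarization.  BN and DN presets are identical in non-polarized
mode, so their non-separation holds by construction.

**What the generator does not model**: pigment networks, streaks and
other organized dermoscopic structures; hair and rulers; color; camera
optics.  The polarized presets also separate the groups more sharply
than clinical cohorts do — the three entropy distributions end up fully
disjoint at n = 166, so rank tests saturate — whereas real feature
distributions overlap substantially.  Passing tests therefore
demonstrate that the *pipeline* faithfully measures and statistically
resolves the intended structural signals, not that the presets are a
model of real lesions.

## Numerical and degenerate-input choices

- GLCM entropy functions validate normalization (|Σp − 1| ≤ 1e-8).
- Offsets leaving no valid pixel pair, empty run-length matrices, Ng < 2,
  and groups with n < 3 raise descriptive errors.
- Run scanning uses a sentinel level 0 between scan lines so runs cannot
  cross line boundaries; levels are 1-based throughout.
- Feature extraction of the full 996-ROI cohort is vectorized
  (bincount-based pair counting and run decomposition) and runs in about
  two minutes on one CPU; tests and the acceptance script use this full
  study size for the cohort-pattern checks and smaller ROIs (8–128 px)
  for oracle and property checks.

## Known limitations

- Absolute feature magnitudes depend on `Ng`, the displacement distance,
  direction handling and the normalization rule; published tables from
  other software are treated as ordering evidence only, and bit-exact
  replication of any external tool is out of scope.
- The Shapiro–Wilk gate makes the omnibus route data-dependent; at large
  n it routes to Kruskal–Wallis for even mild non-normality.  This is the
  intended conservative behavior, documented in the report output.
- JPEG inputs are accepted but warned against: lossy artifacts perturb
  co-occurrence statistics.
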