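# Methods

`dichroma` reconstructs the evolutionary history of male and female
coloration on a time-calibrated phylogeny and decomposes changes in sexual
dichromatism into male-driven and female-driven components. This note
documents the model, the estimators, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Color representation

Each species/sex phenotype is a **CIELAB centroid**: the per-axis mean of a
large random sample of pixels (default 50,000) from an image of the animal.
CIELAB is approximately perceptually uniform, so Euclidean distance (Delta E)
between two colors measures how different they look, independent of where
they sit in color space; the axes are therefore never rescaled. Dichromatism
is the full vector between the sex centroids,

    D = c_m - c_f,     ||D|| = Delta E,

kept as a vector so its *direction* can be used downstream. **Sign
convention.** D points from the female to the male centroid. The convention
matters: with it, the projection s defined below is exactly the first-order
time-derivative of ||D||, so positive s always means the sexes are diverging.
(The opposite convention would force sign gymnastics in every projection
formula; this choice is verified numerically in the test suite.)

The sRGB-to-CIELAB conversion (D65, 2-degree observer) is implemented in the
package with the reference white derived from the sRGB primary matrix itself,
which places neutral grays exactly on the a = b = 0 line; published rounded
white points leave grays a few 1e-3 off axis, enough to contaminate exact
monochromatism checks. The conversion agrees with scikit-image's `rgb2lab`
to better than 0.01 everywhere.

Background handling: pixels that are fully transparent, or that exactly
match a designated background color, are excluded before sampling — only the
organism's pixels are informative. Sampling is without replacement when the
foreground is large enough, with replacement otherwise (fixed sample size).
A monochromatic species depicted by a single image is sampled once per sex
with the same seed, so both sexes get the identical sample.

The shared 50-color k-means palette and its traveling-salesman ordering
(arbitrary insertion + two-edge exchange over cluster centers in CIELAB) are
visualization aids only; nothing downstream depends on them.

## Phylogenetic ridge regression

Let X be the (tips x branches) matrix with X[i, b] = length of branch b if b
lies on the root-to-tip-i path, else 0. For one sex, tip centroids y (per
axis) are modelled as

    y = mu 1 + X beta + e,

so each branch carries its own rate beta_b (CIELAB units per Myr) and
ancestral states are partial sums of rate x length down the tree. Since a
bifurcating tree has 2n-2 branches for n tips, the system is always
under-determined; the rates are estimated by ridge regression,

    min  ||y - mu 1 - X beta||^2 + lambda ||beta||^2,

with the root state mu unpenalized. The penalty simultaneously identifies
the system and shrinks rate variance across branches. Traits are **not**
standardized before fitting: the three CIELAB axes share a perceptual unit
and no mean-variance relationship is expected for color.

Implementation: with an unpenalized intercept, the fit is equivalent to
ridge on column-centered X against centered y, plus mu = ybar - xbar' beta.
The centered design depends only on the tree, so its SVD is computed once
per tree and reused across axes, sexes, penalty values, and permutation
replicates; each fit is then O(n x rank).

**Penalty selection.** lambda minimizes the exact leave-one-out
cross-validated squared prediction error of tip values (computed from the
SVD leverages), on a 31-point log-spaced grid spanning from
(smallest singular value)^2 x 1e-4 to (largest)^2 x 1e3, followed by one
21-point local log-scale refinement — deterministic given the inputs. Two
guards/choices:

* CV error is declared infinite wherever any leverage exceeds 1 - 1e-3.
  Because p > n, the fit interpolates as lambda -> 0 and the LOO identity
  e/(1 - h) degenerates to 0/0 there, producing a spurious minimum at the
  grid edge. This is a guard against an undefined quantity, not a tuning
  threshold.
* **One lambda is shared across the three color axes and across the two
  sexes**, chosen by minimizing the summed CV error of both sexes. A common
  penalty across axes keeps the 3-D rate vector geometrically meaningful; a
  common penalty across sexes is essential because the headline statistic is
  a *ratio of rate magnitudes between the sexes*: fits shrunk by different
  amounts have incomparable magnitudes. In experiments, per-sex CV penalties
  on the same tree occasionally differ by orders of magnitude, in which case
  the ratio measures differential shrinkage rather than differential
  evolution (a male-driven simulation can then even appear female-driven).

Zero-length branches are rejected at input (their rates are unidentifiable);
`read_tree(..., collapse_zero_branches=True)` collapses them into polytomies
first.

## Decomposition of dichromatism change

Each branch has a male rate vector m, a female rate vector f, and an
ancestral dichromatism vector D evaluated at the branch's **parent** node
(the state before the change along the branch). With Dhat = D/||D||:

    s_m =  m . Dhat        male effective rate of dichromatism change
    s_f = -f . Dhat        female effective rate
    s   = s_m + s_f = (m - f) . Dhat

s equals, to first order in branch length, the difference in ||D|| between
the derived and ancestral phenotypes per unit time; shared color drift
(m = f) cancels exactly. Summary statistics:

* **Rate ratio** mean ||m|| / mean ||f|| over branches (> 1: male color
  evolves faster).
* **OLS of log(||m||/||f||) on ancestral ||D||**; a positive slope means the
  rate imbalance grows where dichromatism is high. The slope is
  algebraically identical to the sex x dichromatism interaction in the
  stacked regression log(rate) ~ dichromatism x sex, which the tests verify
  to 1e-10 against an independent statsmodels fit.
* **Contribution slopes**: OLS (with intercept) of s_m on s and of s_f on s.
  Because s = s_m + s_f row-wise, the two slopes sum to exactly 1; equal
  contributions give 0.5 each, a male-driven history pushes the male slope
  above 0.5.

Degenerate cases: branches whose ancestral ||D|| < 1e-9 have no defined
projection direction; their projections are set to 0, the branch is flagged,
and it is excluded from the contribution regressions. Branches with a rate
magnitude below 1e-12 are excluded from the log-ratio regression (log of
zero), with the count recorded. On data that are monochromatic everywhere
the contribution regressions raise an error rather than returning numbers.

Granularity: statistics are computed over **all branches** by default; a
`tips_only` switch restricts to terminal branches for a per-species reading.
Both are supported because the two scatters one would plot (per branch vs
per extant species) answer slightly different questions; all-branch is the
default as it uses the full reconstruction.

## Permutation inference

The null hypothesis is that the labels "male"/"female" carry no information:
within each species the two centroids are exchangeable. Each permutation
replicate swaps the sex labels of every species independently with
probability 1/2 (phylogeny and within-species color pairs untouched) and
re-runs the *entire* pipeline — including penalty re-selection — so the null
distribution reflects every estimation step. Per-replicate seeds are spawned
deterministically from the master seed.

Two-tailed p-values re-center each statistic at its theoretical null value
(rate ratio at 1, compared on the log scale; log-ratio slope at 0;
contribution slopes at 0.5) and use the add-one estimator
p = (1 + #{|null - c| >= |obs - c|}) / (R + 1), which is never 0 and is
exact for exchangeable data. Default R = 1000; the tests use R = 99-199.

## Phylogenetic signal

Pagel's lambda for per-species dichromatism ||D||: an intercept-only
phylogenetic linear model with covariance sigma^2 C_lambda, where
C_ij = depth of the MRCA of tips i and j and C_lambda multiplies the
off-diagonal of C by lambda in [0, 1]. mu and sigma^2 are profiled out
analytically; lambda is found by bounded scalar minimization (tolerance
1e-6) with an explicit comparison against the endpoints 0 and 1 (the
bounded search alone can stop short of a boundary optimum). The confidence
interval is a **parametric** bootstrap (simulate from the fitted model,
re-estimate, percentile interval, default R = 1000); a nonparametric
resampling of tips is not meaningful for a covariance-structured model.

## Synthetic data generator

The generator produces the study conditions every pipeline stage is tested
under:

* **Tree**: Yule (pure-birth) process conditioned on n tips, with one extra
  exponential waiting time after the n-th lineage so terminal branches are
  strictly positive, rescaled to a root age of 100 Myr (the order of the
  root age of the European butterfly radiation). Tree shape conditioned on
  n is independent of the birth rate; the BM process is self-similar in
  time, so the root-age choice only sets units.
* **Colors**: on each branch of length t, both sexes receive a shared
  Brownian increment (SD sigma_shared sqrt(t) per axis, default
  sigma_shared = 3) plus independent sex-specific increments (default
  sigma_sex = 1) — color evolution is mostly shared between the sexes, as
  in real butterflies. The root color is (50, 0, 0), mid-gray.
* **Drive**: in `darwinian`/`wallacean`/`mixed` scenarios, disjoint clades
  covering ~30% of tips are selected; within each, the driven sex is
  displaced by drive_strength x t (default 2 CIELAB/Myr) along one fixed
  random unit direction per clade — sustained directional selection toward
  a new color, which is what builds persistent dichromatism. The clade stem
  branch is included.
* **Monochromatism**: 15% of tips have their sex-specific deviations
  cancelled on the terminal branch so the sexes match exactly, mirroring
  real datasets where many species are exactly monochromatic (same image
  sampled for both sexes).
* Defaults (150 tips, sigma 3/1, drive 2) were chosen once to resemble the
  scale of observed dorsal dichromatism in European butterflies — tip
  Delta E of order 10-40 with strongly correlated sexes — and are stated
  here as the package's study conditions.

Ground truth (every per-branch increment, driven clades, directions, mono
tips) is stored; replaying increments from the root reproduces tip values
exactly. Simulated colors are unbounded internally and clipped to the CIELAB
gamut box only on export, avoiding boundary artifacts in rate estimation.
With the same seed, a Wallacean run *is* the Darwinian run with sex labels
exchanged (the driven sex always consumes the same random draws), so the
pipeline's label symmetry can be tested exactly.

**What the generator does not emulate**: pixel-level image noise (tip
centroids are generated directly), phylogenetic uncertainty (one fixed
tree), measurement error at the tips, selection models beyond constant
directional drive (no OU pull, no mimicry dynamics), and any relationship
between color and ecology. Passing the recovery tests therefore shows the
estimator chain attributes simulated signal correctly, not that real
butterfly data satisfy the model.

## Known limitations and honest failure modes

* The per-branch contribution slope is a noisy functional under a strong
  shared component: its null (no-drive) sampling distribution around 0.5
  has sd ~0.12 at 150 tips even though its expectation is 0.5 (slopes
  computed from the *true* simulated increments scatter even more, sd
  ~0.35). The ridge smoothing concentrates it — a penalty-multiplier scan
  shows the CV-chosen lambda is near-optimal in this respect — but
  individual no-drive datasets can still yield slopes near 0.3 or 0.7.
  Point estimates of the contribution slopes on a single dataset should
  therefore always be read together with their permutation p-value, which
  is calibrated (the test suite verifies approximate uniformity of null
  p-values).
* The ridge penalty rule here (exact LOO CV, shared across sexes) is this
  package's own choice; other implementations of phylogenetic ridge
  regression use different internal criteria, so rate values are comparable
  across packages only qualitatively.
* Problem sizes in the test suite: recovery runs use 150 tips and 20 seeds
  per scenario; permutation calibration uses 200 studies of 50 tips at
  R = 99; lambda recovery uses 200-tip trees. These sizes give the various
  Monte-Carlo checks comfortable margins while keeping the default test run
  quick.
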