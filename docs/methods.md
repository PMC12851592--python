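# Methods

## Pair-correlation estimation

For a pattern of N points in a rectangular window W, the estimator counts
ordered pairs into half-open distance bins [r, r+Δ) and normalises each bin
by the expected pair-distance measure of a binomial (CSR) process:

    ĝ(bin) = count(bin) · |W|² / (N² · ∫_bin 2πr γ̄_W(r) dr)

with γ̄_W(r) = WH − (2r/π)(W+H) + r²/π the isotropised set covariance of a
W×H rectangle (valid for r ≤ min(W, H); the integral has a closed-form
antiderivative π·WH·r² − (4/3)(W+H)·r³ + r⁴/2). Far from the boundary this
reduces to the textbook annulus normalisation N·ρ·π[(r+Δ)²−r²]. We chose
this denominator-level translation normalisation over per-pair edge weights
because it is exact for rectangles, costs nothing, and keeps the estimator a
plain histogram: without it, mean ĝ for CSR fixtures at our default
geometry (r_max = 25 μm in a 200 μm field) falls to ≈ 0.92 because annuli
near the border leave the window, and the CSR calibration property the rest
of the toolkit relies on would not hold.

r_max is additionally capped at 25% of the smaller window side: beyond that
the set-covariance model still holds but per-bin counts thin out and the
variance is dominated by a handful of long pairs. The identical estimator is
applied to empirical and null patterns, so any residual small-sample bias
cancels in like-for-like comparisons.

Degenerate inputs: fewer than two points raises an insufficient-data error;
bin boundaries are half-open so a pair at exactly r = k·Δ lands in the upper
bin.

### Null ensembles and curve comparison

The null for "order beyond steric exclusion" is random sequential adsorption
(RSA): uniform proposals accepted unless within d_min of an accepted point,
matched to the observed pattern's window and point count. d_min is the mean
nipple diameter of the source and is always passed explicitly. RSA jams near
area fraction ≈ 0.55 in 2D; requests whose disks would cover ≥ half the
window fail fast with a saturation error that reports the achieved count.
Proposal acceptance uses a cell grid of side d_min (3×3 neighbourhood
lookup), which makes placement linear in N without changing the accepted
sequence.

Two identically binned curves are compared with the two-sided Wilcoxon
signed-rank test on per-bin differences (zero bins dropped; all-zero → p = 1
by convention). A caution discovered during validation: per-bin g values
within one curve are positively correlated through shared large-scale
density fluctuations, so when both curves are single empirical replicates
the signed-rank p-value is anticonservative (measured ≈ 36–62% rejection at
α = 0.05 for CSR replicate pairs, growing with N). The test is therefore
best read as descriptive when comparing one empirical curve against a
smooth ensemble-mean reference — the use it is put to here — and the
decision-grade call is the R² score below. The signed-rank is also nearly
blind to purely oscillatory deviations (positive and negative bins balance),
another reason the R² score carries the deviation call.

The R² order score against a reference curve is 1 − Σ(g−g_ref)²/Σ(g−ḡ)²
(possibly negative for gross mismatch); empirical curves with R² < 0.9
against their hard-core null are called significantly more ordered than
steric exclusion alone explains. A constant empirical curve has no variance
to explain and raises an undefined-score error rather than returning ±∞.

Curves from several eyes of one genotype are averaged bin-wise before
modelling.

## Hard-core disk model fitting

The model (g = 0 below the contact distance d; damped cosine about 1 above,
phase zero at r = d) is discontinuous in d, so joint gradient optimisation
is ill-posed. d is fitted on a grid with step Δ/2 spanning (Δ/2, r_max/2];
at each grid point (A, λ, P) are solved by bounded nonlinear least squares
(tolerance 1e−8, ≤ 10⁴ evaluations) over the bins with r ≥ d, from a
three-point multistart in P (the heuristic initial P₀, its half and its
double) because the cost is multimodal in the period and a single start can
lock onto a harmonic. Grid points are then ranked by the total squared error
over all bins, counting sub-d bins as (g_emp − 0)²: if the sub-d region were
excluded from the ranking as well, moving d outward would discard exactly
the bins that misfit and a grid point near d_true + P could tie the true
one. Ties resolve to the smallest d. Default bounds: A ∈ [0, 10],
λ ∈ (0, r_max], P ∈ (Δ, r_max].

Initial values are read off the curve: d₀ = smallest r with g > 0.5,
A₀ = max(g) − 1, P₀ = spacing of the first two prominent local maxima
(prominence ≥ max(0.05, 0.1·A₀), which keeps per-bin noise wiggles from
posing as oscillation peaks), falling back to 2·d₀ when only one peak
exists; λ₀ = P₀. A curve with max g ≤ 1 has no peak to anchor the fit and
raises an initialization error; optimisation failure is reported through
`converged=False`, never an exception.

Noiseless curves generated from the model are recovered exactly (≤ 1e−8
relative); at per-bin Gaussian noise σ = 0.05 the median absolute parameter
error is ≈ 2% (50 replicates).

## Circular statistics and stratified permutation inference

Angles are treated as full-circle directional data (period 360°), not axial:
the rhabdomere trapezoid has a chirality, so 10° and 190° are different
orientations. Ventral-eye angles, when a `side` column is present, are
mirrored into the dorsal frame (θ → 360° − θ) before pooling, because the
dorsal and ventral halves rotate in opposite senses about the equator; the
pipeline flag `mirror_ventral` (default on) controls this. A
`pure_genotype` column, when present and the corresponding filter flag is
on, restricts the analysis to ommatidia whose outer photoreceptors are all
of one genotype.

The mean resultant length R is the norm of the average unit vector; R = 0
(antipodal cancellation or uniformity) flags the mean direction as
undefined rather than reporting an arbitrary angle.

Watson's two-sample U² is computed from the combined circular order:
U² = (nm/N²)·Σ(d_k − d̄)², where d_k is the difference of the two sample
ECDFs at the k-th combined point. Centring on d̄ makes the statistic exactly
invariant to a common rotation of both samples (verified against a
brute-force oracle that evaluates every starting rotation) and to label
order. With ties across samples, d is evaluated at the end of each tie
group — both ECDFs jump together — so identical samples give U² = 0 exactly.

Inference is permutation-only. Genotype labels are shuffled independently
within every eye (each permutation resamples all eyes), preserving per-eye
group sizes exactly; the source protocol's "10⁴ permutations per eye" is
read here as 10⁴ total label permutations, each reshuffling every eye,
rather than 10⁴ per stratum.
With k permuted statistics ≥ the observed (ties counted, conservative),
p = (k+1)/(n_perm+1), bounded below by 1/(n_perm+1). Eyes containing only
one genotype carry no label information and are excluded with a warning.
The permutation engine is vectorised (an n_perm × N label matrix with
cumulative-sum evaluation of U² rows), which is what makes the calibration
experiments below affordable.

Calibration measured by simulation at the study design (8 eyes, 5 + 5
ommatidia per eye): type-I error 0.054–0.062 at α = 0.05 over 500 null
datasets with 2000 permutations; power ≈ 1.0 against a pure dispersion
contrast (equal means, von Mises κ = 8 vs 0.5).

## Morphometrics

Circularity is computed on exact polygon geometry (shoelace area via
shapely, vertex-chain perimeter), not on pixel masks; the regular-hexagon
benchmark π√3/6 ≈ 0.9069 is recovered to machine precision, and values for
digitised outlines will differ slightly from mask-based image-tool values
because discrete perimeters are convention-dependent. Self-intersecting or
zero-area polygons raise geometry errors. Bead calibration is a single
multiplicative scale (nominal diameter / measured pixel diameter), averaged
over beads when a frame contains several. The KS comparison switches from
the exact to the asymptotic p-value at combined n = 50, matching the small
per-eye samples this design produces.

## Phototaxis

Tubes are indexed by the number of light approaches (0–3); the scored
quantity is the tube-3 fraction. The independent-trials model (each fly
passes each trial with probability p, so the expected score is p³) is a
simulation fixture for testing the scorer, not a biological claim about fly
behaviour; it reproduces the observed ≈ 50% control final-tube fraction at
p ≈ 0.794. Group summaries report mean, SD (absent for single-assay groups)
and n; no multiple-comparison adjustment is applied, and reports carry a
note saying so, since post hoc testing happens downstream in standard
statistics software.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume:
short-range order with a hard minimum separation (jittered hexagonal
lattice; Gaussian jitter, out-of-window points discarded as in a cropped
SEM field), steric-exclusion-only nulls (RSA), nested von Mises angles (one
stratum per eye; κ = 0 gives circular uniformity), noisy hexagonal cornea
outlines, and binomial three-trial assay outcomes. Defaults mirror the
source study design where it states one — 8 eyes per genotype, 5 ommatidia
per eye, ~35 flies per assay, 3 light trials — and otherwise use field-
realistic magnitudes (0.5 μm nipple spacing and ~0.35–0.5 μm diameters,
20–40 μm SEM fields), chosen once; SEM field size is configurable because
the source protocol does not state it.

They do not emulate: gradients in nipple density across a cornea, fusion or
shape defects of individual nipples, measurement error in angle reading,
correlated ommatidia within an eye beyond the shared stratum, or any image-
level artefact. Passing tests therefore validate the estimators and
inference machinery, not the upstream segmentation, and say nothing about
biological effect sizes.

All generators take explicit integer seeds and are bitwise-reproducible;
there is no global random state. Pipeline reports embed the full
configuration and seed, so identical configs reproduce byte-identical
reports.

## Problem sizes used in the shipped experiments

The calibration and power experiments run at 500 null datasets × 2000
permutations (type-I), 200 datasets × 2000 permutations (power), 20 CSR
replicates of n = 2000 (estimator calibration), 50 noisy replicates
(parameter recovery) and 1000 simulated assays (phototaxis convergence) —
sizes at which the binomial noise on each reported rate is well inside the
acceptance band around its expectation.
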