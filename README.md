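# ommaquant

Quantitative analysis of compound-eye structure and visual behaviour in
*Drosophila*, for researchers who quantify eye phenotypes from SEM and
sectioned-eye measurements. The package turns four kinds of tabular
measurements — corneal-nipple centroid coordinates, ommatidial orientation
angles, polygon outlines of corneas/nipples, and countercurrent phototaxis
tube counts — into the statistics used to compare wild-type and mutant eyes,
and ships synthetic-data generators so every analysis is testable without
microscope data.

## What it computes

**Spatial order of corneal nipple arrays.** The radial distribution function
(pair correlation) of nipple centroids in a rectangular field,

```
g(r) = pair count in [r, r+Δ) · |W|² / (N² · ∫ 2πr γ̄_W(r) dr)
```

where `γ̄_W` is the window's isotropised set covariance (the normalisation
reduces to the familiar `N·ρ·π[(r+Δ)²−r²]` away from the boundary and keeps
`g ≡ 1` for complete spatial randomness out to the r_max cap of 25% of the
smaller window side). Observed arrays are compared against density-matched
hard-core null simulations (random sequential adsorption at the mean nipple
diameter `d_min`) by a per-bin Wilcoxon signed-rank test and by an R²
deviation score with the 0.9 decision boundary. Quasi-ordered arrays are
summarised by fitting the hard-core disk model

```
g(r) = 0                                        r < d
g(r) = 1 + A·exp(−(r−d)/λ)·cos(2π(r−d)/P)       r ≥ d
```

whose parameters are interpretable packing descriptors: minimum spacing `d`,
first-peak amplitude `A` (packing tightness), order decay length `λ`, and
oscillation period `P` (preferred neighbour spacing).

**Ommatidial orientation.** Angles of the R1–R3 rhabdomere trapezoid
relative to the eye equator are directional data; each group is summarised
by the circular mean direction μ and mean resultant length `R ∈ [0, 1]`
(0 = uniform, 1 = perfect alignment). Two-genotype comparisons use Watson's
two-sample U² (sensitive to both location and scale on the circle) or the
resultant-length difference |R₁ − R₂|, with significance from a stratified
permutation null that shuffles genotype labels only within each eye —
preserving the nested eyes-within-genotype sampling — and the small-sample
correction `p = (k+1)/(n_perm+1)`.

**Morphometrics.** Polygon shape descriptors (area, perimeter, equivalent
diameter, circularity `4πA/P²`; a regular hexagonal cornea scores
π√3/6 ≈ 0.907), pixel-to-μm calibration from fiduciary microspheres of known
diameter, bristle phenotype tallies, and two-sample Kolmogorov–Smirnov
comparisons of size distributions.

**Phototaxis.** Benzer-style countercurrent scoring: the reported statistic
is the final-tube fraction — flies that approached the light in all three
trials — with an independent-trials model (`E[fraction] = p³`) backing the
simulator.

## Worked example

Simulate a wild-type-like nipple field (hexagonal lattice, 0.5 μm spacing,
0.04 μm positional jitter, 40×40 μm field), estimate its RDF against 20
hard-core null simulations, and fit the disk model:

```
$ ommaquant simulate --kind hex --out control.csv --seed 1 \
    --window-size 40 --spacing 0.5 --jitter-sd 0.04
wrote 7376 points to control.csv

$ ommaquant rdf --points control.csv --window control.window.json \
    --bin-width 0.025 --r-max 2.5 --null-sims 20 --d-min 0.35 --seed 2 \
    --out control_rdf.csv
wrote mean g(r) over 1 pattern(s) to control_rdf.csv
R² vs null mean: 0.2066 (deviates: True)

$ ommaquant fit-hardcore --rdf control_rdf.csv
{
  "d_um": 0.4625,
  "A": 1.3785401600723146,
  "lambda_um": 1.7615179041323974,
  "P_um": 0.4428285089889586,
  "r_squared": 0.7893018935774081,
  "converged": true
}
```

Reading the output: the array's RDF shares only 21% of its variance with the
hard-core null (R² = 0.21 < 0.9), so its order goes well beyond steric
exclusion. The fitted minimum spacing (0.46 μm) and oscillation period
(0.44 μm) recover the lattice spacing minus jitter, and the first-peak
amplitude A ≈ 1.4 quantifies how tightly neighbours pack; disordered
(mutant-like) fixtures with larger jitter fit systematically smaller A.

Other subcommands: `orient` (circular summaries + stratified permutation
tests from an angle CSV), `shapes`, `bristles`, `phototaxis`, and `run-all`
for a YAML-configured pipeline whose JSON reports embed the full config and
seed for byte-identical reproducibility.

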