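# Methods

## The steady-state theory

The pentagon food web couples five plankton compartments with linear
(type-I) interaction terms: autotrophic flagellates and heterotrophic
prokaryotes compete for phosphate, nanoflagellates (HNF) graze
prokaryotes, ciliates graze both flagellate groups, and copepods close the
web from above.  All biomasses are carried in phosphorus units
(nmol-P L⁻¹), which makes yields dimensionless except the prokaryote yield
on dissolved organic carbon, `Y_BC` (nmol-P nmol-C⁻¹).

Setting growth equal to loss for HNF and for autotrophs and eliminating
the predator terms yields the closed forms implemented in
`pentaweb.foodweb`:

* `B = α_C C / (Y_H α_H)` — prokaryote biomass is set entirely by
  predation balance, linear in ciliate biomass `C`;
* `P = (α_C/α_A) C` — free phosphate rises linearly with `C` because
  ciliates crop the autotrophs that would otherwise draw it down;
* `μ = α_B P` — phosphate-limited prokaryote growth.

Bacterial carbon demand is production over yield, `BCD_P = μB/Y_BC =
kC²` with `k = α_B α_C²/(Y_BC Y_H α_H α_A)`.  Because consumption of
labile DOC cannot sustainably exceed its supply rate ψ, the realized
demand is `BCD = min(kC², ψ)`.  The crossover `C* = sqrt(ψ/k)` separates
mineral-nutrient-limited (MNL) from organic-carbon-limited (OCL) growth.
The tie `kC² = ψ` is classified OCL, so the regime label is
right-continuous in `C`; tests assert `MNL ⟺ C < C*` under exactly this
convention.

### Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| α_B | prokaryote P affinity | 0.08 | L nmol-P⁻¹ h⁻¹ |
| α_A | autotroph P affinity | 0.04 | L nmol-P⁻¹ h⁻¹ |
| α_H | HNF clearance on prokaryotes | 0.0015 | L nmol-P⁻¹ h⁻¹ |
| α_C | ciliate clearance on flagellates | 0.0005 | L nmol-P⁻¹ h⁻¹ |
| Y_H | HNF yield on prokaryotes | 0.3 | – |
| Y_BC | prokaryote yield on DOC | *configured* (example 0.006) | nmol-P nmol-C⁻¹ |
| σ | P per ciliate cell | 0.00043 | nmol-P cell⁻¹ |
| Q10 | rate temperature sensitivity | 1.3 | – |
| ψ | labile-DOC supply | *configured* (example 3.0) | nmol-C L⁻¹ h⁻¹ |

The rates are reference values at 17 °C.  `Y_BC` and ψ are free
parameters of the theory with no canonical values; the package refuses to
construct a parameter set without them.  The shipped example uses
`Y_BC = 0.006` (growth efficiency ≈ 0.3 at biomass C:P ≈ 50) and `ψ = 3.0`,
which puts `C* ≈ 4.02` nmol-P L⁻¹ (≈ 9.4 cells mL⁻¹), mid-range of the
ciliate abundances the synthetic mesocosms span.  Both numbers are
illustrative package choices, not measurements.

σ is recomputed from first principles in `ciliate_p_content`: a 20 μm
equivalent sphere at 0.13 pg-C μm⁻³ and molar C:P = 106 gives
4.28 × 10⁻⁴ ≈ 0.00043 nmol-P cell⁻¹.

Temperature enters as a single net factor `f = Q10^((T−17)/10)`.
`temperature_scale` multiplies each α by `f` (yields, σ and ψ are
temperature-independent here), and `bcd_cells` applies the same net factor
to the quadratic coefficient: the coefficient contains three α's in the
numerator and two in the denominator, so its net power in the rates is
one.  Where the temperature correction sits typographically is ambiguous
in the source material; the net-factor convention is the dimensionally
consistent reading and is applied uniformly.

## The dynamic reconstruction

The steady-state theory only pins down the bilinear grazing skeleton; the
ODE system in `pentaweb.dynamics` fills in the remaining closure terms and
keeps them all inside one function (`derivatives`) for auditability:

* Liebig growth for prokaryotes, `μ_B = min(α_B P, Y_BC a_D D)`, with a
  labile-DOC pool `D` and a cell-specific DOC clearance `a_D`
  (default 0.005 L nmol-P⁻¹ h⁻¹ — its value shapes transients and the
  depth of DOC drawdown but cancels from every steady state);
* ciliate yield `Y_C = Y_H` by default; copepods as a fixed specific loss
  on ciliates, or a hard clamp (`clamp_ciliates`) that treats ciliate
  biomass as the boundary condition imposed by the copepod stock;
* egested fractions `(1−Y)` and copepod export routed to an explicit sink
  pool `S`, so that total phosphorus `P+A+B+H+C+S` is conserved exactly in
  a closed run — a property the tests check to 10⁻⁶ relative.

On the closed forms the HNF and autotroph balances vanish identically
(asserted to 10⁻¹⁴), and clamped-ciliate runs converge to the closed-form
`B` and `P` within 10⁻³ relative.

### Dosing

Glucose additions are daily impulses of `multiplier × 106 ×` the
phosphate dose, following the enrichment design.  The daily mineral-P
addition, however, is applied as a continuous rate by default
(`phosphate_mode="continuous"`; impulses remain available).  The reason is
a known artifact of linear uptake kinetics: `μ = α_B P` has no maximum
growth rate, so an instantaneous P spike transiently pushes the P-limited
rate above the C-limited rate in *every* tank, which would manufacture a
spurious glucose response in tanks that the theory says should be
indifferent (MNL).  Real cells saturate; spreading the dose preserves the
regime contrast the model exists to express without adding a μ_max
parameter the theory does not contain.

### Scenario sizes

Equilibrium-equivalence checks clamp ciliates at 30, 60 and 120
nmol-P L⁻¹ with a continuous P supply of twice the prokaryote demand.  At
these levels the B–H predator–prey pair is damped at a rate of order μ
(0.03–0.12 h⁻¹), so a trajectory started at twice the equilibrium
prokaryote biomass settles to 10⁻³ relative well before t = 2000 h.  At
very low ciliate levels the same pair is so weakly damped that desk-scale
convergence tests are not meaningful; the regime-emergence check
therefore starts *on* the closed-form equilibrium and verifies that the
realized long-run DOC consumption tracks `min(kC², ψ)` (to 5%) across a
ciliate sweep spanning the crossover, which exercises the DOC side of the
dynamics without waiting out a slow predator–prey spiral.

### Mesocosm emulation

`synth.simulate_experiment` runs one clamped-ciliate tank per design unit
from the quasi-steady state consistent with ongoing dosing (daily P dose
25 nmol-P L⁻¹ d⁻¹, ambient labile DOC 100 nmol-C L⁻¹), imposing ciliate
biomasses of 1 ("low", MNL) or 7 ("high", OCL) nmol-P L⁻¹.  Counts are
derived with per-cell P quotas (prokaryote 1.6 × 10⁻⁸, HNF 1.4 × 10⁻⁶,
ciliate 4.3 × 10⁻⁴ nmol-P), giving realistic magnitudes (~10⁵–10⁶
prokaryotes mL⁻¹, ~10 ciliates mL⁻¹).  Flow-cytometry-style virus groups
are stylized: group I (small, prokaryote-infecting) equals the prokaryote
count times a virus-to-prokaryote ratio of ~10 that rises with ciliate
abundance, groups II–IV are fixed fractions of group I.  Observation
noise is multiplicative lognormal with unit mean (counts are positive and
FCM errors scale with the signal).

## The fingerprint pipeline

Binary band matrices (samples × bands) stand in for DGGE (bacterial 16S)
and PFGE (viral genome-size) gels.  Band calling, gel normalization and
image processing are upstream of this package: inputs are assumed
already-called and aligned.

* **Jaccard** dissimilarities (via `scipy.spatial.distance.pdist`) require
  every sample to carry at least one band; an all-zero row is an error,
  not a silent drop.
* **NMDS** minimizes Kruskal stress-1 by alternating a Guttman (SMACOF)
  update with monotone regression of configuration distances on
  dissimilarity ranks (pool-adjacent-violators via
  `scipy.optimize.isotonic_regression`).  Ties are handled in the primary
  fashion: tied dissimilarities are ordered by their current configuration
  distance, leaving the fit unconstrained within a tie block.  Defaults:
  k = 2, 20 restarts (restart 0 from classical scaling, the rest random),
  tolerance 10⁻⁷ on the stress change, 500 iterations.  A Guttman step
  that would raise stress-1 terminates the run, keeping stress-1 monotone
  within a run; the best restart is returned, centered and rotated to
  principal axes.  An independent gradient-descent minimizer over the same
  rank constraints reproduces the attained stress to 10⁻³ in tests.
* **Procrustes** uses the symmetric convention: both configurations are
  centered and scaled to unit sum of squares before the optimal
  rotation/scaling, `m² = 1 − (Σ singular values)²` and the correlation is
  `sqrt(1 − m²)`.  This matches `scipy.spatial.procrustes` to 10⁻¹⁰, which
  serves as the independent oracle.
* **protest** permutes the row order of the second configuration;
  p = (1 + #{permuted ≥ observed})/(n_perm + 1), so p is never 0.  On
  n = 3 the Monte-Carlo p agrees with full enumeration of all 6
  permutations.
* **The coupling ensemble** repeats {NMDS of both matrices → protest}
  `n_repeats` times and reports the median p, the percentage of
  repetitions with p < 0.05, and the median Procrustes correlation.
  Within one repetition both NMDS fits share one fresh seed; repetitions
  are seeded independently (`numpy` SeedSequence spawning).  This makes
  two identical matrices superimpose exactly (correlation 1) in every
  repetition — with fully independent fits they would not, because small
  binary distance matrices have near-tied NMDS optima with genuinely
  different geometry.  An alternative reading of "repeated permutations"
  (one NMDS pair, permutations only) is available as
  `permutations_only=True`.
* **PERMANOVA** is single-factor: Gower-centered squared distances,
  `pseudo-F = (SS_between/df_b)/(SS_within/df_w)`, `R² = SS_between/SS_total`,
  permutation p over label shuffles with the +1 convention.  The
  pseudo-F matches both a direct-summation oracle (10⁻¹⁰) and the
  scikit-bio implementation in tests.  Two-factor designs are analysed as
  separate marginal single-factor fits.
* **Pearson/VPR**: `scipy.stats.pearsonr` (two-sided t-test on n−2 df)
  with explicit errors for constant series; VPR is the elementwise ratio
  of small-virus to prokaryote counts.

### Calibration design

The protest p-value for one fixed dataset pair is essentially a property
of the data — re-running the NMDS moves it only slightly.  The fraction of
significant repetitions for a *single* null pair therefore concentrates
near 0 or 100, not at the nominal α.  Null calibration is consequently
measured across independently generated dataset pairs: the fraction of
pairs whose ensemble median p falls below 0.05 is compared with the
binomial 99% interval around 5%.  Type-I error of protest and PERMANOVA
themselves is measured directly on independent Gaussian configurations
and on unstructured random band matrices (≥ 500 replicates), using the
rejection rule p ≤ α: with discrete permutation p-values on a grid of
1/(n_perm+1), `P(p ≤ α) = α` exactly whenever α is a grid multiple, so
this is the exactly calibrated check.

### Band-matrix generator

Host bands are independent Bernoulli draws at base presence 0.5; a
treatment contrast shifts each band's probability by ±effect/2 with a
random band-specific sign between the 0× and 3× glucose groups.  Each
virus band maps to one host band and copies it with probability
`coupling`, otherwise it is drawn independently; symmetric bit-flip noise
follows.  Default sizes (12 samples, 30 host and 20 virus bands) match
the scale of real gels.  Rows that come out empty are redrawn (cap 100).
The Bernoulli/flip structure is an explicit stand-in — nothing is known
about the true noise distribution of gel fingerprints, and the generator
makes no attempt at band co-migration, genome-size ladders or gel
physics.  Passing tests demonstrate that the *pipeline* is calibrated and
powerful under this stand-in structure, not that real gels satisfy it.

## The inverse problem

`fit_bcd_curve` recovers (k, ψ) of `min(kC², ψ)` by nonlinear least
squares in log-parameters (`scipy.optimize.least_squares`, tolerances
10⁻¹²), initialized from the 90th percentile of the observations (ψ) and
the median of y/C² over the low-C tercile (k).  Continuity at the
crossover is inherent in the functional form.  A branch supported by
fewer than two observations (all data on one side of the fitted
crossover) is flagged unidentifiable rather than reported as a confident
estimate.  Under 5% multiplicative noise with 50 points spanning both
regimes, median recovery errors are ~1% for both parameters.

## Known limitations

* Linear functional responses throughout: no saturation (μ_max), no prey
  switching, no viral lysis term in the dynamics.
* No diatom/silicate compartment — silicate enters only as a treatment
  label; its ecological effect in the real experiments is interpretive.
* Nitrogen is not modeled (phosphorus is the limiting mineral nutrient);
  the NH₄⁺/NO₃⁻ distinction is likewise metadata only.
* The virus-group generator encodes the association the statistics are
  meant to detect; it is a test harness, not a mechanistic virus model.
* Weak predator–prey damping at low ciliate biomass means equilibrium
  convergence claims are only made for the scenario sizes stated above.
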