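# Methods

This note documents the statistical procedures implemented in `mrphewas`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Design and assumptions

Two-sample MR treats germline variants as instrumental variables for an
exposure: valid instruments must (A) associate strongly with the exposure,
(B) affect the outcome only through the exposure (no horizontal
pleiotropy), and (C) be independent of confounders of the
exposure–outcome relationship. The toolkit works entirely at the
summary-statistic level: exposure effects in SD units of the trait,
outcome effects as log odds ratios from case-control GWAS, so causal
estimates are log-ORs per SD of exposure.

## Instrument selection (`sumstats`)

Filters, in order: association p < `p_max` (default 5×10⁻⁸, genome-wide
significance); minor allele frequency min(eaf, 1−eaf) ≥ `maf_min`
(default 0.01 — rare variants are *excluded*, both because their effect
estimates are unstable and because frequency-based palindrome resolution
needs informative frequencies); F = (β/se)² ≥ `f_min` (default 10, the
conventional weak-instrument screen); then greedy LD pruning against a
user-supplied r² matrix at `r2_max` (default 0.01), always retaining the
variant with the strongest association (smallest p, ties broken by larger
|β| then lexicographic id, making output deterministic). LD is an *input*:
estimating r² from a genotype reference panel is out of scope. Records
with missing eaf are dropped by default (`allow_missing_eaf=False`)
because downstream harmonisation and PVE need frequencies.

## Harmonisation (`harmonise`)

Outcome records are matched by variant id (no proxy search). Allele logic:
exact match → aligned; swapped labels → effect sign and frequency flipped;
complementary-strand labels → resolved by complementing first.
Palindromic variants (A/T, C/G) cannot be resolved by letters, so
orientation comes from allele frequencies: a palindrome is kept only when
both frequencies lie outside 0.5 ± `palindrome_eaf_window` (default 0.08,
a conservative declared default in line with common two-sample practice)
and is re-flipped when the two frequencies sit on opposite sides of 0.5.
All drops carry reason codes and retained + dropped always equals the
input count.

## Estimators (`estimators`)

* **Wald ratio** (single instrument): β̂ᵧ/β̂ₓ with first-order delta SE
  se(β̂ᵧ)/|β̂ₓ|; a second-order variant adding the exposure-uncertainty
  term is available and differs by <5% for F > 10.
* **IVW-RE** (primary): weighted regression through the origin, weights
  1/se(β̂ᵧ)². Random effects are *multiplicative*: the SE is scaled by
  √max(1, Q/(n−1)), the convention of standard summary-MR toolchains; it
  never deflates below the fixed-effect SE. An additive
  (DerSimonian–Laird on Wald ratios) variant sits behind
  `method="additive"`. One instrument falls back to the Wald ratio with a
  flag.
* **Weighted median**: per-instrument ratios ordered, weighted by inverse
  first-order ratio variance; the estimate interpolates the ratio at
  cumulative weight 0.5. SE by parametric bootstrap (resampling β̂ₓ, β̂ᵧ
  from their sampling normals; seed mandatory; default 1,000 draws).
  Consistent when ≥50% of weight comes from valid instruments.
* **Mode-based estimate**: argmax of a normal-kernel density over the
  ratios on a deterministic 512-point grid spanning the ratio range ±3
  bandwidths; bandwidth = φ × 0.9·min(sd, MAD/0.6745)·n^(−1/5) (modified
  Silverman; φ default 1). The default is the *simple* mode (equal
  weights); inverse-variance weighting is behind `weighted=True`. The
  point estimate is deterministic; only the bootstrap SE is stochastic.
  Zero ratio dispersion returns the common ratio.
* **MR-Egger**: instruments re-oriented so all β̂ₓ ≥ 0 (the orientation in
  which a directional pleiotropic mean is defined), then weighted
  regression with a free intercept. Both intercept and slope use the same
  multiplicative overdispersion floor as IVW, with p-values and CIs from t
  on n−2 df — appropriate at the small instrument counts where Egger is
  typically read.
* **Leave-one-out**: IVW refits omitting each instrument, reporting the
  variant whose omission shifts the estimate most.

Wald/IVW/WME/MBE intervals use the fixed normal multiplier 1.96.

## Directionality and PVE (`inference`)

The Steiger test compares instrument R² on the exposure against R² on the
outcome: r = √R² values are Fisher-z transformed and compared by a
two-sample z test with variances 1/(n−3); `direction_true` means the
instruments explain more of the exposure, the pattern expected under
exposure → outcome causation. For continuous traits
R² = Σ 2p(1−p)β² (capped at 1). For case-control outcomes each log-OR is
first converted to the liability scale using the population lifetime risk
K: log-OR → risk difference b·K(1−K) → liability effect by division by the
normal density at the threshold Φ⁻¹(1−K). A K-free probit-style
conversion (b·√3/π) is behind `method="probit"`. Steiger is computed for
continuous exposures only; binary exposures get "not assessed", which by
construction closes the robust/probable gates. Lifetime risks are
configuration inputs; the placeholder default K = 0.04 is in the range of
common-cancer lifetime risks and should be replaced per outcome in real
analyses.

## Power (`inference.power`)

Normal-approximation power for a two-sample MR test of a binary outcome:
non-centrality ncp = log(OR_SD)·√(N·R²·φ(1−φ)) with φ the case fraction
(N·φ(1−φ) is the case/control harmonic mean), and
power = Φ(ncp − z₁₋α/₂) + Φ(−ncp − z₁₋α/₂). This is exactly the inverse
of the asymptotic IVW variance under the generator's SE model, so analytic
predictions and empirical rejection rates close the loop; the formula was
validated against simulation rather than transcribed. Power equals α at
OR = 1 and is symmetric in log-OR. Empirical IVW-RE rejection sits
slightly *below* the analytic value at intermediate powers (worst gap
≈ 0.1 on the test lattice) because the multiplicative random-effects floor
inflates roughly half of the SEs; the analytic curve describes the
fixed-effect test.

## Evidence grading (`grading`)

Continuous exposures, evaluated in order with *strict* inequalities:

| tier | gate |
|---|---|
| robust | p_IVW < α/m, (p_WME < 0.05 or p_MBE < 0.05), true direction, >1 IV |
| probable | as robust but p_IVW < 0.05 |
| suggestive | p_IVW < 0.05 (multi-IV) or p_Wald < 0.05 (single IV) |
| non-significant | otherwise |

The robust threshold defaults to α/m with m the number of continuous
traits actually screened; a fixed denominator (e.g. m = 3,500, giving
1.4×10⁻⁵ at two significant figures) is available for comparability with
large published screens. The suggestive tier deliberately does not require
direction concordance. Binary exposures — whose two-sample effect sizes
are unreliable — are classified supported (p < 0.05) / not supported, with
ORs carried through for reporting only. No between-trait correlation
adjustment is made; grading is conservative in that respect.

## Literature triangulation (`litspace`)

Terms are normalised (lowercase, trimmed, whitespace-collapsed; no
ontology mapping) and triples de-duplicated. The default join is
*directed*: a mediator is a term appearing as the object of an exposure
triple and the subject of a cancer triple (chain exposure → M → cancer);
an any-position symmetric join is behind a flag since overlap could also
be read undirected. Anchor terms are never reported as mediators.
Mediators are ranked by min(support on either side), ties alphabetical. A
space is viable iff it holds strictly more than `min_triples` (default
50). The module operates on exported TSVs; live semantic-database queries
are out of scope so everything is deterministic and offline.

## Synthetic data (`simulate`)

The generator works directly at the summary level under the standard
model: independent instruments (consistent with post-pruning data),
eaf ~ U(0.05, 0.5), true per-SNP exposure effects ~ N(0, 0.05), exposure
GWAS of n = 300,000 (large-biobank scale), outcome GWAS of 73,673 cases /
86,854 controls (a large colorectal-cancer consortium scale). Those
defaults put 30 instruments at a total PVE around 3%, matching the median
instrument strength of real trait panels, with typical F well above 10.
Sampling SEs use the asymptotic forms se_x = 1/√(2p(1−p)n) and
se_y = 1/√(2p(1−p)·Nφ(1−φ)); observed effects add seeded Gaussian noise
and p-values are consistent with β/se. Pleiotropy assigns a direct
outcome effect α ~ N(mean, sd) to a configurable invalid fraction
(balanced: mean 0; directional: mean ≠ 0). An individual-level
liability-threshold simulation exists in the test suite as an oracle for
the PVE conversion, not as part of the generator.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: LD between instruments, winner's-curse
inflation of discovery effect sizes, sample overlap between exposure and
outcome GWAS, population stratification, and allele-frequency differences
between studies (exposure and outcome frequencies are generated equal).

Calibration under these conditions (500 replicates, 30 instruments,
measured by the acceptance suite): IVW-RE, WME and Egger reject a true
null at ≈ 0.03–0.05, within binomial 99% bounds of the nominal 0.05;
IVW-RE recovers a true log-OR of 0.2 with negligible bias and ≈ 0.94–0.96
CI coverage; the Egger intercept recovers a generative directional
pleiotropy mean of 0.02; Steiger calls the generative direction in
essentially all replicates at ≥10:1 PVE ratios.

## Numerical choices

P-values are floored at 10⁻³²⁰ to stay in (0, 1]; exported −log₁₀ p is
capped at 300. The MBE grid has 512 points; argmax ties resolve to the
lowest grid value. Clustering of the Z matrix uses complete-linkage
agglomeration on Euclidean distances (the defaults of the familiar R
heatmap tooling), with missing cells treated as 0 (neutral evidence) for
distances only; pairwise-complete distances are behind a flag. Labels are
pre-sorted so dendrogram output is permutation-invariant. ORs are exported
at 6 significant figures.

Problem sizes in the test and acceptance suites (500 calibration
replicates, 300 pleiotropy replicates, 200 Steiger replicates, a 27-point
power lattice at 300 replicates per point, bootstraps of 100–200 draws)
are the package's chosen desk-scale defaults; all are seeded and
deterministic.

## Known limitations

* The simple mode-based estimate is **strongly conservative** under the
  null in these conditions: measured rejection ≈ 0.002–0.006 at α = 0.05
  (the weighted variant ≈ 0.01). This mirrors the behaviour reported for
  the original mode-based method and is a property of the estimator with
  bootstrap SEs, not a defect of the grading chain — p_MBE only ever
  enters grading as a < 0.05 sensitivity gate, where conservatism cannot
  create false robust/probable calls.
* Directional pleiotropy is only identifiable relative to
  exposure-increasing allele coding; MR-Egger re-orients instruments
  internally, so a pleiotropic mean simulated under mixed coding behaves
  as balanced.
* The Wald-ratio SE is first-order; with weak instruments (F near 10) it
  understates uncertainty slightly (second-order variant available).
* No MR-PRESSO-style outlier removal, multivariable MR, or
  contamination-mixture models; the leave-one-out screen is the only
  outlier diagnostic.
* Binary-exposure estimates are reported but not effect-graded, and power
  is not computed for binary exposures.
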