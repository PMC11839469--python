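# Methods

`rubiscan` reimplements, as a tested pipeline, the analysis of a
growth-coupled deep mutational scan (DMS) of rubisco: from barcoded
sequencing counts across a CO₂ titration to per-variant fitness, inferred
CO₂ affinity (K̃_C) and maximal-velocity ratio (Ṽ_max), together with the
supporting barcode→variant mapping, conservation profiling and in-vitro
kinetics calculations.  Every stage is exercisable on synthetic data with
known ground truth; no external sequencing data are required.

## Selection model

The host strain grows on glycerol only when rubisco carboxylation supplies
flux out of a dead-end metabolite, so growth rate reports enzyme activity.
We model the growth rate of a variant as linear in its carboxylation
velocity relative to wild type,

    μ(v) = μ_dead + (μ_WT − μ_dead) · v/v_WT ,

capped at μ_max.  Under log-phase growth, the totals-normalized log₁₀
read-count ratio of a variant, rescaled so the pooled wild-type barcodes
sit at 1 and the median of a catalytic dead panel sits at 0, equals
v_mut/v_WT in expectation.  With Michaelis–Menten kinetics this gives the
ratiometric titration curve

    e_norm([CO₂]) = Ṽ_r · (K_C,WT + [CO₂]) / (K_C,mut + [CO₂]) ,

with Ṽ_r = Ṽ_max,mut/Ṽ_max,WT and K_C,WT fixed at the literature value of
149 μM.  Ṽ_r confounds turnover number and expression level (V_max =
k_cat·[enzyme]); K_C does not, which is why affinity is the better-posed
inferred parameter.

## Enrichment statistic

For variant j, over its barcodes i passing a count threshold
(max(N₀,ᵢ, N_f,ᵢ) ≥ c_min, i.e. observed either pre- **or**
post-selection),

    e_j = median_i [ log₁₀((N_f,i + N_f,tot·α_p)/(N₀,i + N₀,tot·α_p))
                     − log₁₀(N_f,tot/N₀,tot) ] ,

where totals include unassigned reads and the pseudo-count constant α_p is
scaled by the totals.  The median over an even number of barcodes is the
mean of the two central values.  Normalization divides by the wild-type
minus dead-median span; wild type maps to 1 exactly and, for an odd dead
panel, the dead median maps to 0 exactly (to ~1 ulp for an even panel).
The dead median is recomputed per condition and replicate.  Variants with
no passing barcode are emitted as missing (NaN), never as zero, and are
dropped per replicate-pair in correlations and per point in fits.

The processing parameters are chosen by a 2-D sweep maximizing the mean
pairwise Pearson correlation across replicates (averaged over conditions);
correlations within 1e-10 are treated as tied and broken toward smaller
c_min, then smaller α_p.  Defaults c_min = 5, α_p = 3.65×10⁻⁷ are the
sweep-optimized values for the original dataset and are overridable.

## Titration fit and reliability

`fit_titration` minimizes equally weighted squared residuals of the
ratiometric curve over all replicate points jointly, with box constraints
Ṽ_r ∈ [0, 10] and K_C ∈ [10⁻², 10⁴] μM.  The objective is evaluated
vectorized on a 5×5 log-spaced start grid plus one data-driven start
(Ṽ_r from the highest-CO₂ response at wild-type K_C); bounded
least-squares refinement (`scipy.optimize.least_squares`, TRF, analytic
Jacobian) is launched from the best `n_refine` starts and the lowest final
objective wins, ties broken toward smaller K_C.  Solutions at a bound are
flagged pinned.  On noiseless curve data the fit recovers parameters to
relative 10⁻⁶ across Ṽ_r ∈ [0.1, 2], K_C ∈ [30, 1500] μM.

Because inferred affinities of weak variants are sensitive to (c_min, α_p),
each variant is refit across the full sweep (11 c_min values linear 0–50 ×
10 α_p values log 10⁻⁹–10⁻⁶) combined with 10 subsamplings of the
replicates (drawn with replacement to the original replicate count), i.e.
1,100 bootstrap fits per variant.  Enrichments are recomputed once per
grid cell and shared by that cell's subsamples.  Bootstrap fits whose K_C
is pinned at a bound are excluded from the K_C sample — a value at the box
constraint is not an estimate, and without this rule dead variants would
report a spurious CV of 0.  The figure of merit is a quartile-based
coefficient of variation, IQR/(1.349·|median|) — the Gaussian-consistent
robust σ/μ, reconciling the two descriptions "s.d. over the mean" and
"quartile-based"; a plain σ/μ is available by configuration.  A variant is
reliable iff CV < 1.  The point estimates are the sweep medians of K_C and
Ṽ_r; a variant with no usable (unpinned) fit in more than half the sweep
cells reports CV = ∞.  Whether the point estimate should instead be a
single best-parameter fit is not determinable from the source analysis;
the sweep median is the more robust choice and is what the bootstrap
quartiles describe.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated:

- **Library**: a reference protein (synthetic sequence, catalytic residues
  pinned at the canonical positions 166/191/193/194/287/329) with all 19
  substitutions at every mutable position; a full 466-residue scan
  enumerates 8,835 variants.  Each variant, and wild type, carries a
  configurable number of unique random 30-nt barcodes (default 20).
- **Kinetics prior**: mutant k_cat ratios lognormal(−0.35, 0.35) capped at
  1.15 (gains beyond ~15% of wild type are not observed in this system);
  K_C lognormal around 149 μM (σ = 0.6) truncated to [30, 1500] μM, the
  identifiable range of the titration; expression factors lognormal
  (σ = 0.2); a 25% "null" fraction at 2% activity emulating unfolded
  mutants and giving the characteristic bimodal fitness distribution;
  dead-panel mutants at exactly zero velocity.  Unbounded priors are not
  merely unrealistic but break the assay: a single variant a few
  lognormal σ above wild type would take essentially the entire
  post-selection multinomial pool.  The growth cap μ_max = 1.5·μ_WT
  serves the same purpose at the growth level.
- **Growth**: μ_WT = 0.45 h⁻¹ and μ_dead = 0.02 h⁻¹ (residual background);
  these endpoints are not reported for the real system and cancel from the
  normalized enrichment — only their gap sets the dynamic range.  Selection
  time is set so wild type completes log₂100 ≈ 6.64 doublings (the
  assayed "100-fold expansion"), per condition.
- **CO₂ grid**: {0.3, 0.7, 1.5, 3, 5, 10}% gas phase converted by Henry's
  law, C = p·K_H(25 °C)·exp[2400·(1/T − 1/298.15)] with K_H = 0.0334
  mol L⁻¹ atm⁻¹, giving ≈1,223 μM at 5%/37 °C.  The titration levels of
  the original experiment are not published; this grid spans the wild-type
  K_C about fivefold in each direction.
- **Counts**: pre-selection barcode abundances lognormal (σ = 0.5,
  emulating bottlenecking), drawn per biological replicate; reads
  multinomial at the configured depth per condition and timepoint (counts
  sum to the depth exactly).  An infinite-depth mode returns expected cell
  counts with n_post = n_pre·e^{μt} for closed-form checks.
- **Reads**: long reads are flank + barcode + flank + coding sequence with
  i.i.d. substitution errors on the coding region; the barcode region is
  emulated as accurately read, since grouping reads by barcode is treated
  as solved upstream and would otherwise be impossible at a 10% raw error
  rate.  Short reads are barcode amplicons.  Same seed, same bytes.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: PCR jackpotting and chimeras, barcode sequencing
errors and collisions, expression–mutation interactions beyond a scalar
factor, oxygenase side reactions, condition-dependent expression, and any
deviation from exponential growth.  Recovery accuracies measured here are
upper bounds for real experiments.

## Barcode mapping

Long reads are grouped by exact 30-nt barcode between fixed flanking
anchors; barcodes with support below `min_support` (default 3 — the
original threshold is unpublished) are dropped.  The consensus is the
per-position majority base; ties become ambiguous and invalidate the
barcode.  A consensus is retained as wild type (amino-acid level, so
synonymous changes pass) or as exactly one designed substitution; any
additional or undesigned change invalidates the barcode.  Counting of
short reads is by exact barcode match — no error correction, since random
30-mers make collisions negligible — with non-matching reads tallied to an
unassigned bucket so that retained + unassigned = total exactly.

## Conservation

Conservation of a reference position is the maximum over amino acids of
the fraction of sequences carrying that amino acid in the aligned column.
Gaps and non-standard residues are excluded from the denominator by
default (the convention is switchable); columns where the reference is
gapped are skipped, giving a 1:1 position↔column map.  The
conservation-fitness comparison uses the mean normalized enrichment of the
≤19 mutants per position and Spearman rank correlation, with quantile-cut
outlier panels (conserved-yet-tolerant, variable-yet-sensitive).

## In-vitro calculations

- **Initial rates**: candidate windows (every 5th start; lengths 10/20/40%
  of the trace) are scored by linear-fit R² × fraction of the total
  monotonic A₃₄₀ decrease covered; the winning slope is converted by
  |slope|/(ε·path)/2 for the 2:1 NADH:carboxylation stoichiometry of the
  coupled assay.  ε·path is a calibration input (plate-reader NADH
  standard curve).  Baseline shifts cancel; non-decreasing traces return 0
  with a warning.
- **Michaelis–Menten fits**: `scipy.optimize.curve_fit` with positivity
  bounds; standard errors from the covariance diagonal; day-replicates are
  concatenated and fit jointly (equal weights make pooling exact).  The
  triplicate error band fits median−s.d., median, median+s.d. rate sets.
- **CABP titration**: linear regression of rate vs inhibitor; k_cat =
  y-intercept/x-intercept, which reduces algebraically to the slope
  magnitude; non-declining rates are an error.
- **Specificity**: S_C/O = ν_C[O₂]/(ν_O[DIC]).
- **Bicarbonate→CO₂**: Henderson–Hasselbalch with configurable pKa′
  (default 6.35).  Published bicarbonate→CO₂ ranges for this assay are not
  reproducible with any single pKa′, so the conversion is exposed as a
  utility with explicit parameters rather than hard-coded.

## Problem sizes and numerical choices

The validation simulation uses a 30-residue reference (551 designed
variants + wild type), a 3-position dead panel (57 mutants), 20
barcodes/variant, 3 replicates, 6 CO₂ levels and 10⁶ reads per condition
and timepoint; the reliability sweep on it uses a reduced 3×3×3 grid
(c_min × α_p × subsamples), a scale at which the full bootstrap machinery
is exercised end to end while the whole suite stays fast.  The full
11×10×10 sweep is validated on a 50-variant subset.  Under these
conditions the pipeline attains median relative K̃_C error ≈ 2% among
reliable variants, correct direction of ≥2-fold affinity shifts for ≈97%,
Spearman ≈ 0.97 between fitness and k_cat×expression, and ≈80% of
low-activity variants correctly flagged unreliable — the corresponding
test thresholds (≤20%, ≥90%, ≥0.9, >50%) are deliberately not tuned to
these margins.

Degenerate inputs are handled explicitly: empty designs, zero read depth,
zero totals, fewer than two usable CO₂ levels, degenerate normalization
(wild type equals dead median) and non-declining CABP lines all raise
typed errors; consensus ties, boundary-pinned fits and undefined
correlations are flagged rather than silently resolved.

## Known limitations

- Ṽ_max estimates confound k_cat and expression by construction; the
  package does not attempt deconvolution.
- Oxygenase activity is not modeled anywhere in the selection (the in-vitro
  S_C/O calculation is independent of the DMS model).
- The consensus caller assumes substitution-only errors (equal-length
  reads); indel-containing long reads are dropped at extraction rather
  than aligned.
- The sweep's bootstrap treats replicates as exchangeable units; there is
  no hierarchical model of barcode-level noise.
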