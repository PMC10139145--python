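# Methods

## The measurement being modelled

A nanoDSF instrument ramps a 10 µL sample from 35 to 95 °C while recording
intrinsic fluorescence at 330 and 350 nm. Unfolding exposes buried
tryptophans to solvent and red-shifts their emission, so F350 gains and F330
loses intensity through a transition; the ratio F350/F330 is the standard
dye-free unfolding coordinate, and melting temperatures are read off as
apexes of ∂(F350/F330)/∂T. For tear fluid the profile of this derivative
shows two reproducible apexes, T1m and T2m, whose positions shift in
glaucoma (T1m down, T2m up). The package reproduces this measurement chain
computationally.

## Mechanistic scan model (`tfdp.thermo`)

Each protein is a reversible two-state unfolder with van't Hoff free energy

    ΔG(T) = ΔH_vH · (1 − T/Tm)        (temperatures in kelvin)

so the unfolded fraction f_U(T) = 1/(1 + exp(ΔG/(R·T))) is logistic with
midpoint Tm and sharpness set by ΔH_vH. A channel signal is the
concentration-weighted superposition

    F_λ(T) = Σᵢ cᵢ · (1 + β_λ,ᵢ·(T − 35)) · (a_λ,ᵢ + d_λ,ᵢ·(2·f_U,ᵢ(T) − 1)),

with per-unit-concentration mean emission a_λ, folded↔unfolded contrast d_λ
(d₃₅₀ > 0 > d₃₃₀, so the ratio rises through a transition) and an optional
linear baseline drift β_λ. Multiplicative Gaussian noise (1 + σ_rel·ε) is
applied independently per point and channel; σ_rel = 0 gives deterministic
output.

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| Tm (LYZ, LCN1, IgA, HSA, LTF) | 67.8, 69.4, 72.9, 75.1, 67.4 °C | measured single-protein melting midpoints of the five core tear proteins |
| ΔH_vH | 800 kJ/mol (all species) | not measured for these samples; chosen so the derivative peak FWHM (≈4.4 °C) resolves the CONTROL mixture's low-Tm group (67.4/67.8/69.4) from its high-Tm pair (72.9/75.1) into exactly two detectable peaks, while staying in the physically plausible range for 14–80 kDa proteins. 600 kJ/mol leaves the high-Tm apex with relative prominence 0.01, below the 0.05 detection floor. Configurable per species. |
| a₃₃₀ = a₃₅₀ | 1.0 RFU/(µg/mL) | arbitrary scale; the ratio cancels it |
| d₃₅₀ = −d₃₃₀ | 0.01 | the ratio of two affine functions of f_U is a Möbius transform whose derivative apex sits ≈ 2·d·R·Tm²/ΔH_vH above Tm; at 1 % contrast this bias is ~0.025 °C, far inside the 0.1 °C reporting resolution. The class invariant caps contrast at 5 %; at 4 % the bias (~0.11 °C) already exceeds the reporting step. |
| baseline slopes | 0 | drift adds a constant to the derivative and does not move apexes; kept for realism experiments |
| σ_rel | 0.002 | shot-like relative noise per 0.1 °C point, matching visually clean instrument ratio traces |
| ligand shifts | myristate: HSA→80.3, LYZ→55.6; Fe³⁺: LTF→95.0; latanoprost: none | measured end-state Tms at saturating ligand (100 µM myristic acid, 1 mM Fe(III) citrate); binding is modelled as binary, with no titration, because only end states are known |

The mixture presets CONTROL (140 µg/mL HSA, 110 LTF, 50 LYZ, 30 IgA,
100 LCN1) and POAG (110/150/30/30/60) follow the published physiological
compositions verbatim, including their internal tension with the prose
description of glaucomatous composition shifts; they are not "corrected".

**Limitations (by design).** Linear superposition cannot produce mixture
peaks outside the span of component Tms. Measured tear mixtures show exactly
that emergent behaviour (a second apex above every component Tm, and an
Fe³⁺-induced 90.3 °C mixture peak); those effects require interaction terms
that are out of scope. A green mixture test therefore establishes that the
*pipeline* resolves two peaks from a five-component superposition — not that
the simulator reproduces measured mixture peak positions.

## Phenomenological cohort model (`tfdp.cohort`)

Cohort-level analyses need profiles whose (T1m, T2m) can be placed exactly
at chosen values, which the mechanistic model cannot do for mixtures. The
two-peak generator builds the ratio directly:

    ratio(T) = b + s·(T − 35) + A₁·Λ((T − t1m)/w₁) + A₂·Λ((T − t2m)/w₂)

with Λ the logistic CDF, F330 a linearly decaying level, F350 = ratio·F330,
and the same multiplicative noise model. Derivative apexes sit at t1m and
t2m exactly when the transitions are separated by ≥ 6·max(w).

Shape defaults: amplitudes A = 0.25 per transition, widths w = 0.8 °C
(derivative FWHM ≈ 2.8 °C), baseline 0.85, slope 5·10⁻⁴ /°C, F330 level
1000 RFU decaying 0.2 %/°C, σ_rel = 0.002. Widths, amplitudes and the
derivative smoothing window (below) were calibrated **jointly, once**, to
the package's stated robustness requirement — at σ_rel = 0.002 the detected
apexes must stay within 0.2 °C of the noiseless detection in ≥95 % of 200
seeded replicates — because apex jitter scales as (noise slope)/(peak
curvature) ∝ w³/A and no parameter set with broad, low-amplitude transitions
meets that requirement. The resulting profile (total ratio swing 0.5,
derivative peaks ≈ 0.08 /°C) is at the sharp end of, but within, the range
of real tear traces. What a green cohort test establishes: the extraction
and clustering machinery recovers biomarkers whose generating values are
known. What it does not establish: anything about real between-patient
covariance, skewness, third peaks, or instrument drift, none of which are
simulated.

Cohorts draw per-subject (t1m, t2m) from class-conditional Gaussians —
defaults at the observed patient cluster averages, control-like (67.9, 77.7)
and POAG-like (64.6, 79.3) °C, SD 0.8 °C (within-cluster spread is not
published; 0.8 °C is a stand-in) — with rejection resampling enforcing
t1m < t2m − 4 °C, nuisance-shape jitter, and per-subject random streams
derived as `SeedSequence((cohort_seed, subject_index))` so datasets are
bit-reproducible across platforms. Labels are encoded CONTROL = 0, POAG = 1.

## Six-curve construction (`tfdp.io`)

Runs are aligned to a common grid (default 35–95 °C at 0.1 °C) by an
interpolating cubic spline, exact at the original knots, with extrapolation
refused. The ratio is computed from the raw resampled channels (matching the
instrument's output order); the three derivatives use Savitzky–Golay
smoothing-differentiation, polynomial order 3, window 5.0 °C (51 points).
The window choice is the noise/bias compromise discussed above: the SG
derivative noise gain falls from 1.52 (15-point window) to 0.50 (51 points),
and 5.0 °C remains comfortably below the ~10 °C peak separation, so every
noiseless melting-temperature round trip in the library is still exact at
the 0.1 °C reporting resolution. Edge values use one-sided polynomial fits
(`mode="interp"`), which keeps boundary peaks detectable.

## Peak detection (`tfdp.features`)

Candidates are local maxima of d(ratio)/dT with prominence ≥ 5 % of the
curve's span (the published analyses do not state how peaks were found; this
floor and the 71 °C single-peak split temperature — the midpoint of the
typical T1m ≈ 65 °C and T2m ≈ 78 °C — are explicit stand-ins). A monotone
run terminating at a grid edge adds a boundary candidate at the edge
temperature, flagged censored; the run must span ≥ 1.5 °C because the
one-sided edge fits amplify noise and would otherwise produce spurious
censored peaks. With more than two candidates the two most prominent are
kept; interior apexes are refined by three-point quadratic interpolation
(offset clipped to ±half a step, degenerate curvature falls back to the grid
point) and reported to 0.1 °C, the reporting precision used for patient
data. Flat curves yield an empty pair rather than an error. Profiles missing
either peak are flagged and excluded from clustering; censored peaks are
used as-is (a Tm reported at the scan limit is still a Tm).

## Clustering (`tfdp.cluster`)

2-means on raw °C coordinates (both axes are temperatures on the same scale;
whether the original analysis standardized is unstated, so no-standardization
is the default and a `standardize` switch is provided). Lloyd's algorithm,
squared Euclidean distance, 50 restarts each initialised with two distinct
sampled points, empty clusters reseeded to the farthest point, best inertia
kept, deterministic given a seed. The lower-T1m center is named POAG-like;
T1m ordering alone keys the naming because it determines T2m ordering in all
relevant configurations. Tests cross-check the optimum against exhaustive
partition enumeration (≤ 8 points) and against scikit-learn's k-means.

## Classification (`tfdp.classify`)

Feature vectors concatenate the six curves subsampled every 0.5 °C (121
points × 6 = 726 features; order F330, F350, ratio, dF330, dF350, dratio).
The pipeline standardizes on the F350/F330 ratio throughout (one published
passage says F330/F350 for the learner inputs; the two are monotone
transforms of each other and carry the same information). Four learners run
with fixed published hyperparameters — LR (max_iter 1000), SVC (poly kernel,
degree 1, C = 1, gamma "auto"), random forest (500 trees), AdaBoost (100
rounds over depth-3 trees) — on a stratified 5-fold split shuffled once per
seed and shared by all learners. Z-scoring is fit per training fold only.
The reported interval is mean fold accuracy ± 1.96·SD(folds)/√5 (the "95 %
of the average" convention read as a normal-approximation CI; SD uses
ddof = 1). Confusion counts pool out-of-fold predictions;
sensitivity = TP/(TP+FN) and FPR = FP/(FP+TN) are reported to 0.1 %, with
zero denominators flagged rather than raised. The published hyperparameter
search ranges are not re-searched; the best-found values are hard defaults.

Note on the permutation null: cross-validated accuracy under permuted labels
is biased slightly *below* 50 % (training and test folds are anticorrelated
under permutation), so individual null runs can graze the lower edge of the
binomial chance band at small n; the regression suite checks band coverage
over 20 seeded permutations (≥ 18/20 per learner) at a reduced feature grid
to stay inside the CI budget.

## Reproducibility

Every stochastic step takes an explicit seed: scan noise, cohort generation
(per-subject child streams), k-means restarts, and the CV shuffle. The
pipeline writes a manifest (config echo, seeds, package version, dataset
checksum) and two runs with identical configuration produce byte-identical
result payloads.

## Known limitations

- No ΔCp curvature, aggregation/scattering channel, or unfolding
  irreversibility in the thermodynamic model.
- Ligand binding is all-or-none; no binding-constant titration.
- No multi-peak (> 2) deconvolution; three-peak profiles keep their two most
  prominent apexes.
- No third diagnostic class, covariate simulation, or model selection over k.
- Published patient-cohort accuracies (e.g. AdaBoost ≈ 81 %) are not
  reproducible here: the patient scans are unreleased, and synthetic cohorts
  are by construction either easier or harder than the clinical data.
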