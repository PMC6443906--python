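# Methods

## Generative model of a synthetic cohort

The generator emulates a TMT 6-plex cohort study of skeletal muscle.  Donors are
organized in labeling sets of five (one per age stratum: 20–34, 35–49, 50–64,
65–79, 80–95 years) plus one pooled reference channel (channel 131).  The log2
reporter intensity of spectrum *s* (peptide *j* of protein *p*) in the channel
of donor *i*, set *b*, is

    m_p + e_j + β_PA,p·PA_i + β_age,p·age_i + β_BMI,p·BMI_i + u_pb + L_bc + ε_sc

with batch intercepts u ~ N(0, τ²) per (protein, set), loading offsets L per
(set, channel), peptide ionization offsets e, and spectrum noise ε.  The
reference channel carries the covariate-free profile m_p + e_j + u + L + ε.
Intensities are exponentiated to the linear scale and mixed through the
isotopic-impurity matrix (`observed = P @ true`), mirroring real PSM exports;
the pipeline inverts that mixing and applies the log2 transform itself.

Defaults are the study conditions: 60 donors in twelve sets; activity-effect
magnitudes for non-null proteins drawn U(0.02, 0.22) log2-units per activity
point with random sign, bracketing the per-activity-point effect range such
studies report; σ_spectrum = 0.20, τ_batch = 0.05, loading SD = 0.10, peptide
offset SD = 0.30 log2-units, chosen once as typical reporter-level variability
for TMT spectra; nuisance rates of 5% decoys, 2% contaminants, 3% shared
spectra, 3% channel-blanked spectra, 5% set-incomplete peptides, 2% high
peptide/protein FDR records and 20% single-engine peptides.  Questionnaire
records are constructed to realize a target of weekly MVPA minutes exactly
(whole sessions with the final activity absorbing the remainder at a
power-of-two session count, so scoring round-trips in exact floating point);
casual walking is generated independently and never counts toward MVPA.

The four myosin heavy chains (MYH7, MYH1, MYH2, MYH4) are always simulated with
deep, complete peptide coverage and clean identification fields — they are the
most abundant proteins in muscle lysates and must survive filtering for the
fiber-type covariate to exist.  Donor-level fiber-composition differences are
emulated as per-(myosin, donor) shifts (SD 0.40 log2-units), which gives the
fiber-ratio covariate realistic between-donor variance; the myosins' own
activity effects are zero so the covariate stays exogenous.

What the generator does **not** emulate: correlated missingness, intensity-
dependent noise, ratio compression from co-isolation interference, peptide
modifications, protein-protein abundance correlation, and donor dropout
(cohorts must fill sets completely).  Passing tests therefore demonstrate
correctness of the computation under the stated model, not robustness to every
artifact of real TMT data.

## Retention rules

Rules run in a fixed order (decoy; contaminant; peptide FDR ≤ 0.001; protein
FDR ≤ 0.01; shared spectra; incomplete channels; peptide detected in every
non-reference sample; single-peptide proteins need >1 search engine), each
reporting in/removed/out counts that telescope.  The "detected in every sample"
rule operates at peptide level: because a complete spectrum covers all of its
set's donors at once, the requirement reduces to having at least one retained
spectrum in every donor-bearing set.  An absent channel is an empty field; a
literal 0 intensity is treated as absent, since a detected reporter ion is
never truly zero.  Purity correction precedes filtering and only touches
complete 6-vectors (flagged per record), so completeness is judged on raw
presence.  Filtering is idempotent, and on a nuisance-free cohort removes
nothing.

## Normalization

Within-protein centering subtracts the median over **all** of a protein's
spectrum-by-channel log2 values (reference included), globally across sets.
A per-set variant (`per_set=True`) is available but off by default, for two
reasons established during design: per-set centering removes exactly the batch
effects the model's TMT-experiment term is meant to absorb (making that
adjustment vacuous), and the subtracted per-set median tracks the set's
activity levels, which measurably attenuates between-set effect information
(≈20% downward bias on β at the default noise profile, versus <2% with global
centering).  Roll-up takes one pooled median over all spectrum-level values per
(protein, sample) — not a median of peptide medians — with mean-of-middle for
even counts; loading correction subtracts each sample column's median
(single-pass column centering, not Tukey's iterative polish), asserted to leave
every column median at 0 within 1e-9.

Because medians are nonlinear, channel loading offsets are removed *exactly*
only when protein spectra counts are uniform and other variance sources are
silent; in general they are removed per column while leaving per-(protein)
constants that the model intercept absorbs.  The invariant test isolates
loading offsets under uniform counts, where the final matrix is identical to
the offset-free run to machine precision.

## Covariates

MVPA minutes/week = Σ over brisk walking, weight/circuit and up to four
vigorous activities of (sessions per 2 weeks × minutes per session) / 2; the
ordinal code is 0 (<30), 1 ([30, 75)), 2 ([75, 150)), 3 (≥150), lower edges
inclusive.  The fiber-type ratio is computed on the linear scale,
2^a7 / (2^a1 + 2^a2 + 2^a4): a ratio of log2 values themselves
(`literal_log2=True`) is sign-unstable once abundances are centered around 0,
so the linear reading is the default.  The ratio is computed from the final
(post-polish) matrix.

## Per-protein model

Response: log2 relative abundance across the non-reference samples.  Fixed
effects: activity code as a single numeric slope (0–3), age, BMI, dummy-coded
race (reference = most frequent level, recorded in the output metadata), fiber
ratio; random intercept per TMT set (a `set_effect="fixed"` switch dummy-codes
the set instead).  Estimation is REML with the variance ratio λ = τ²/σ²
profiled: with Q D Qᵀ the eigendecomposition of the set-indicator Gram matrix,
V = σ²(I + λ Z Zᵀ) is diagonal in the eigenbasis, so each profile-likelihood
evaluation is a diagonal weighted regression.  λ is optimized on log-scale over
[e⁻³⁰, e²⁵] by bounded scalar minimization (xatol 1e-9) and compared against
the λ = 0 boundary; at the boundary the fit falls back to OLS with residual
degrees of freedom and must match the closed-form normal-equations solution
(tested to 1e-6).

The activity slope is tested with a t-statistic whose degrees of freedom come
from the Satterthwaite approximation: df = 2f²/Var(f), f = var(c'β̂), with
Var(f) by the delta method in (σ², τ²) using the inverse REML information
matrix — all computed in the same eigenbasis.  Against R's lmerTest on a fixed
synthetic cohort, β and SE agree to 1e-6 and df to ~0.1 (frozen reference
values are kept in the test suite); statsmodels MixedLM serves as a second,
independent cross-check at its own optimizer tolerance.  Zero-variance
covariate columns (e.g. a fiber ratio that is constant by construction in a
noise-free cohort) are dropped with a recorded note; genuine collinearity
raises an error naming the offending columns.  Per-protein failures are
captured in their result row and never abort the sweep.

Significance is raw p < 0.05 for direction calls (up: β > 0; down: β < 0;
β = 0 ties to ns), with Benjamini–Hochberg q-values (statsmodels step-up,
verified against a brute-force implementation) reported alongside.

## Calibration and recovery, as measured by the test suite

On all-null cohorts at study scale (60 donors, ≥5,000 protein fits across 22
seeds) the raw p < 0.05 fraction is ≈0.05 (asserted within [0.03, 0.07]);
myosin rows are excluded from the count because the fiber-ratio covariate is
computed from them.  With activity effects of 0.05, 0.1 and 0.22 log2-units
per point at the default noise profile, estimates are unbiased within 10% of
truth and discovery signs match the generator in ≥95% of cases.  With all
variance components zero, identity crosstalk and no nuisance records, the full
pipeline returns each true β to 1e-6: this requires more than half the
proteins to be exact nulls, so that the column-median polish subtracts exactly
zero.

## Numerical conventions

Medians use mean-of-middle for even counts throughout.  The purity matrix must
be diagonally dominant; correction raises on singular matrices and warns above
condition number 1e6.  All randomness flows through one `numpy` Generator
seeded from the config; identical seeds give byte-identical outputs, recorded
in the run manifest via SHA-256 per table.  Problem sizes in the test suite
(cohorts of 200–300 proteins, up to 22 seeds for calibration) were chosen so
the whole suite completes in well under a minute of simulation per check while
keeping Monte-Carlo error small relative to the asserted bounds.
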