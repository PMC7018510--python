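# Methods

This note records the models implemented in `irlego`, the defaults and why
they were chosen, the numerical choices that affect results, and what the
synthetic-data tests do and do not establish about real data.

## Dual-dye ratiometric thermometry

**Model.** Each dye's emission intensity declines linearly with
temperature around a reference temperature T₀ (default 23 °C, the ambient
bath temperature):

    I_dye(T) = I_dye(T₀) · (1 + s_dye · (T − T₀))

with default sensitivities s_TAMRA = −0.882 %/°C (probe) and
s_FITC = −0.165 %/°C (reference), the values measured in pure dye
solutions. A mixed spectrum is a nonnegative combination of unit-area
pure-dye basis spectra; `unmix_spectrum` recovers the coefficients by
nonnegative least squares (NNLS) on a common wavelength grid. NNLS rather
than clipped ordinary least squares: clipping biases the ratio whenever one
coefficient is near zero. The ratio R = a_TAMRA/a_FITC is declared
undefined when a_FITC < 10⁻⁶ × max(a_FITC, a_TAMRA); callers must branch
on the flag instead of receiving an infinity.

Because both dyes share the excitation path, R is exactly invariant to any
global multiplicative perturbation of the spectrum — the property that
makes two-dye thermometry robust to excitation-power drift, verified as a
property test.

**Calibration.** R(T) is fit by ordinary least squares per medium (water,
3 % agarose, muscle); the media are kept separate even though their fitted
sensitivities are similar, and cross-medium application is the caller's
decision. The *relative* sensitivity is slope/R(T₀). To first order it
equals s_TAMRA − s_FITC = −0.717 %/°C; the exact value over a 25–38 °C ramp
referenced to 23 °C is (s_T − s_F)/(1 + s_F·ΔT_mid)² ≈ −0.738 %/°C because
R(T) is a ratio of two linear laws, hence slightly convex. Both numbers
appear in the tests with the curvature correction derived in closed form.

**Inversion.** Two routes are provided: the calibration-line inversion
T = (R − b)/m used for absolute temperatures, and the first-order
rise formula ΔT = (R_after/R_before − 1)/s_rel used for before/after
heating pairs, with an exact linear-model inversion available behind a
flag. The first-order form under-reads a 10 °C rise by ≈ 0.1 °C at these
sensitivities; the exact form has no such error. Spatial profiles report
ambient (23 °C) plus the measured rise; replicate positions aggregate to
mean ± sd. Smooth lateral curves use a two-term Gaussian model fit by
multi-start nonlinear least squares (8 starts: centers {0, ±half-span} ×
widths {¼, ½ span}; best SSE wins, ties broken toward smaller total
width). Fewer than 7 points is rejected (7 parameters).

**Baseline.** An optional constant-offset subtraction (mean of the lowest
5 % of intensities) exists but is off by default; no baseline model is
assumed.

## Heat diffusion

**Model.** Conductive transfer in a homogeneous infinite medium,
ρc ∂T/∂t = κ∇²T + q. For an ideal point source of absorbed power Q the
closed forms are ΔT(r) = Q/(4πκr) (steady) and the same damped by
erfc(r/(2√(αt))) (transient, α = κ/(ρc)). With water-like α ≈ 1.4·10⁻⁷
m²/s the focal region is above 99 % of steady state within 1–2 s, so
experimental heating on multi-second time scales is effectively a steady
point source.

**Finite-difference solver.** 7-point Laplacian on a uniform Cartesian
grid over [−L, L]³ with Dirichlet ambient boundaries, focus at the center.
Two schemes: explicit FTCS with a CFL check (dt ≤ dx²/6α; violations are
rejected with the corrected step suggested), and backward Euler solved
exactly per step by diagonalizing the Laplacian in the discrete sine basis
(DST-I), which for a constant source collapses the whole trajectory to a
closed-form geometric series — long simulated times cost two transforms.
The source is a Gaussian ball of standard deviation `deposition_radius`
(default 0.36 µm, matching a ~0.4 µm² focal spot), renormalized on the
grid so the injected power is exact; the grid must resolve it
(spacing ≤ radius). Scan mode deposits the time-averaged density uniformly
over the scan extent (default 8 µm × 8 µm) laterally. Energy bookkeeping
(∫ρcΔT dV vs Q·t before boundary contact) closes to well under 1 %.

**Validation.** The FD field matches the analytic transient voxelwise
within 2 % for r ≥ 3 µm at 1 µm spacing; shell-averaged scan and point
profiles agree within 3 % for r well beyond the scan extent (the spherical
average cancels the source's multipole structure), while the focal peak is
substantially lower under scanning — the reason scan heating avoids focal
overheating at equal far-field dose.

**Free parameters and limitations.** `absorbed_power_fraction` (default
0.1) sets what fraction of incident laser power becomes heat; it scales
every ΔT linearly and is *not* constrained by this package — calibrate it
against a measured focal temperature (the worked example uses 0.0044,
which puts a 95 mW beam's focus near 50 °C in tissue). Convection in free
water is approximated by an effective-conductivity multiplier ≥ 1 on the
medium, not by fluid dynamics; transient profiles with the multiplier
reproduce the qualitative contrast that gels/tissue hold steeper gradients
than water, but quantitative water predictions should not be trusted.
Heterogeneous tissue, perfusion and optical propagation are out of scope.

**Confinement radius.** Shell-averaged temperature versus distance from
the focus, with the largest threshold crossing (default threshold 38 °C,
the effective heat-shock-induction temperature) located by linear
interpolation between shells; 0 when even the innermost shell is cold.

## Lineage MLE with background correction

**Model.** A labeled fish's latent lineage class L ∈ {TM, M, T, none}
follows θ on the 4-simplex. Channel c ∈ {T, M} is observed positive iff L
implies it OR an independent background Bernoulli(β_c) fires; control fish
have background only. β is shared between groups. Category probabilities
are therefore products of Bernoullis for controls and a mixture linear in
θ for labeled fish; both sum to one identically. Presence means ≥ 1 GFP⁺
cell (configurable threshold); count magnitudes enter only the rank-sum
comparison, not the MLE.

**Estimation.** The joint multinomial log-likelihood of both groups is
maximized over (θ, β). θ is parameterized by softmax, β by logistic, and
L-BFGS with an analytic gradient runs from 10 random starts plus one at
the empirical labeled frequencies and control rates; probabilities are
clipped to [10⁻⁹, 1−10⁻⁹] before logs (the −∞ of an impossible observed
category is represented by this clip inside the optimizer and returned as
a true −inf by the public likelihood function). Boundary estimates are
legitimate: simulated truths with θ_T = 0 come back ≤ 0.02 at large n.
When the control group has no positive fish at all the MLE has a closed
form (β̂ = 0, θ̂ = permuted labeled frequencies, since category (T+,M−)
maps to lineage T and (T−,M+) to lineage M) and is returned exactly. A
plug-in mode fixes β̂ at the control empirical rates and optimizes θ only;
joint estimation is the default because it uses the labeled group's
double-negative information about β as well.

**Uncertainty.** Nonparametric bootstrap: fish resampled with replacement
within group, percentile intervals, seeded. Degenerate resamples refit via
the closed form and are counted in diagnostics. A simulation study (250
cohorts of 200 fish per group, B = 120, interior truth θ_TM = 0.4) keeps
the realized coverage of nominal 95 % intervals inside 90–98 %; these
study sizes were chosen as the smallest that pin coverage to a few
percent.

**Rank-sum test.** Mann–Whitney–Wilcoxon from midranks. Combined n ≤ 20:
exact enumeration of all group assignments (correct under ties); larger:
normal approximation with tie and continuity corrections; all-tied data
returns p = 1.

## Synthetic-data generator

The generator is the testbed's definition of "truth". Spectra use
synthetic Gaussian basis peaks (FITC-like 519 nm, TAMRA-like 580 nm, sd
15 nm — identifiability placeholders, not measured emission shapes) with
multiplicative lognormal per-bin noise of unit mean (default CV 1 %).
Cohorts default to the study-scale design: 27 labeled / 109 control fish,
θ = (0.4379, 0.2841, 0, 0.2780), β = (0.03, 0.08). GFP⁺ counts in
positive channels are shifted negative binomials (≥ 1): mean 20,
dispersion 1 for lineage-driven positives; mean 2, dispersion 1 for
background positives — deliberately over-dispersed, hence non-normal,
which is why the group comparison uses a rank-sum test. Real count
distributions are not calibrated beyond non-normality, so the count model
is a free choice; only presence/absence feeds the MLE, which insulates the
estimator from it. When a channel is both lineage- and background-positive
the count is drawn from the lineage model (presence logic is unaffected).

What passing synthetic tests shows: the estimators invert the exact
generative models they assume, at the stated noise levels and sample
sizes. What it does not show: robustness to spectral baseline drift, dye
compartmentalization, non-independent background across channels,
fish-to-fish heterogeneity in β, or miscounted cells — all violations of
the generative assumptions that real cohorts may exhibit.

## Reproducibility

All generators and fits are pure functions of (config, seed). Pipeline
runs derive per-stage seeds from a single global seed by hashing the stage
name (CRC32, reduced mod 2³¹), so stages rerun independently yet
reproducibly; manifests record the seeds, input checksums and per-stage
summaries. Problem sizes in the validation script — 70 spectra per
thermometry series, 24 per dye ramp, 50,000 fish per cohort arm — were
chosen so that Monte-Carlo error is comfortably below each comparison's
tolerance.
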