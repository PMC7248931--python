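# Methods

## The dimerization model

Acetic acid vapor is treated as a two-state mixture of monomers M and
cyclic dimers D, 2 M ⇌ D, ideal-gas behavior assumed throughout. The
equilibrium constant K = p_D/p_M² (pressures in atm, standard state
p° = 1 atm, so K is dimensionless and the van't Hoff and mass-action
expressions interoperate without unit juggling) combines with Dalton
closure p_M + 2 p_D = p_tot to give a quadratic in p_M. We evaluate its
physical root in the rationalized form p_M = 2 p_tot/(1 + √(1 + 8 K p_tot)),
which is algebraically identical to the textbook (√(1+8Kp)−1)/(4K) but
remains well-conditioned as K → 0; p_D is then taken from the mass-action
law K·p_M² rather than from (p_tot − p_M)/2, which loses all significant
digits in the monomer-dominated regime.

Monomer/dimer interconversion is fast on the NMR timescale, so the
observed internal shift difference Δδ = δ(OH) − δ(Me) is the
population-weighted average of the two limiting values, with monomer
fraction p_M/p_tot (each dimer carries two monomer units). Working with
the internal difference rather than absolute shifts is what makes
unreferenced gas-phase spectra usable: Δδ is invariant under any global
axis shift, and no reference compound survives both phases anyway.

Temperature enters only through K(T) = exp(−(ΔH − TΔS)/(RT)) with
R = 1.9872041×10⁻³ kcal/(mol·K). ΔH is carried in kcal/mol and ΔS in
cal/(mol·K) — the units the field reports — with the 10³ conversion
internal to `gibbs_energy`. Standard-state ΔG° is evaluated at 298.15 K;
the tabulated per-level thermochemistry reproduces at two decimals only
with 298.15, not 298.

The model deliberately excludes trimers/tetramers (no quantitative
formulation exists for them), activity corrections, and liquid-phase
contributions.

## Pressure calibration

Neither sample geometry has a gauge, so pressure is anchored at one
point and propagated by a model:

* **Anchor**: the Antoine equation log₁₀ p_sat = A − B/(T + C) evaluated
  at the condensation temperature (glass) or at the experiment
  temperature at the instant the liquid has fully evaporated (FEP). The
  shipped acetic-acid coefficients (log₁₀/bar/K dialect, validity
  290–391 K) come from a standard compilation and are stored as package
  data with provenance metadata — coefficients are data, not method, and
  user overrides are accepted. Evaluation outside the validity range
  warns but proceeds, since the 150 °C experiment sits slightly above it.
* **Glass track**: an airtight tube at fixed volume and amount follows
  p_tot = p0·T/T0 (ideal-gas isochore).
* **FEP track**: p_tot(t) = (I(t)/I(t₀))·p0 − p_corr, with I the methyl
  integral. The subtraction constant p_corr absorbs a small spectral
  baseline distortion that otherwise leaves a spurious pressure floor as
  t → ∞; it is a *fitted model parameter*, not preprocessing, and
  experimentally stays below 0.005 atm (the package warns above that).
  Negative corrected pressures (noise undershoot) are clipped to zero
  with a warning rather than raising.

The intensity-ratio track is smoothed with a Savitzky–Golay filter
(3rd order, 21 points) before fitting. The filter passes polynomials up
to its order unchanged, so it cannot bias the low-order trend; widening
the window has a negligible effect on the fitted thermodynamics, which
the test suite checks on synthetic data. Decay-onset detection (t₀) is
a convenience heuristic — argmax of the smoothed intensity followed by a
run of ≥ 10 consecutive decreases — because no operational definition
beyond "the beginning of the pressure decay" exists; t₀ is normally
user-supplied.

## Lineshape processing

Synthetic spectra are generated directly in the frequency domain (the
analysis consumes only peak positions and widths, so FID-domain steps —
apodization, zero-filling — are out of scope). Baseline correction fits
a 5th-order polynomial restricted to peak-free regions found by
iterative 3σ clipping (5 iterations, upward outliers only); any input
that *is* a polynomial of degree ≤ 5 returns identically zero. Peaks are
Lorentzians L(x) = A(w/2)²/((x−x₀)² + (w/2)²) fitted as a sum by
trust-region least squares; OH vs methyl identity is assigned purely by
position order (OH is always the higher-frequency signal here).

## Global fitting

The FEP fit minimizes the unweighted sum of squared shift residuals over
all datasets and time points, with ΔH, ΔS shared, and Δδ_D and p_corr
free per dataset; Δδ_M is fixed to the zero-pressure extrapolation of
the 150 °C dataset (3.76 ppm for acetic acid). Weighting is uniform —
the shift-noise level is temperature-dependent in practice, but no
per-point uncertainties are available to justify anything else.

Optimizer: `scipy.optimize.least_squares` (trust-region reflective),
finite-difference Jacobian, ftol 10⁻¹⁰, xtol 10⁻⁸. Starting values
ΔH = −15 kcal/mol, ΔS = −36 cal/(mol·K), Δδ_D = 10.5 ppm, p_corr = 0:
literature-scale magnitudes; the basin is benign, and the zero-noise
round trip recovers generating parameters to ≲10⁻⁸. Bounds:
ΔH ∈ [−40, 0], ΔS ∈ [−80, 0], Δδ_D ∈ [Δδ_M, 20] ppm,
p_corr ∈ [0, 0.02] atm — the p_corr bound is soft (warning above
0.005 atm) because the experimental statement "always below 0.005 atm"
describes an outcome, not a constraint. A single-temperature ensemble
raises an identifiability error naming ΔH/ΔS: at one T they enter only
through ΔG(T).

The glass fit frees all four parameters; it requires ≥ 6 points spanning
≥ 50 K, the regime where both limiting shifts are constrained. The
monomer-shift extrapolation refits a single-temperature curve in the
(Δδ_M, Δδ_D, log₁₀K) parametrization — at one temperature the
thermodynamics collapse to one number — and requires the sampled
pressures to span more than a three-fold range.

### Monte Carlo uncertainty

The dominant error source is the anchor pressure p0. Each of the (by
default 1000) iterations draws one systematic relative error
ε_sys ~ N(0, 0.10) shared by all datasets and independent per-dataset
errors ε_k ~ N(0, 0.05), rescales p0_k by (1 + ε_sys + ε_k) (non-positive
factors redrawn), and repeats the full global fit. Reported standard
deviations and the ΔH–ΔS covariance are sample statistics over
iterations; ΔG° and its spread are computed from the (ΔH, ΔS) sample
directly, so the strong positive ΔH–ΔS error correlation — forced by the
van't Hoff structure, since the data pin ΔG(T) over a narrow T window —
is honored without linearization. The split into shared and
per-dataset components is an interpretive choice (the source analysis
states only that both contributions exist and behave differently in
propagation); fractional (relative) perturbation is used because the
stated uncertainties are percentages of p0. The stage is deterministic
given its mandatory seed.

## Composite thermochemistry

Correlation energies follow E(X) = E_CBS + A·X⁻³ in the basis-set
cardinal number X; the fit is linear least squares in (E_CBS, A), which
with exactly two cardinals reduces to the closed form
E_CBS = (X³E_X − Y³E_Y)/(X³ − Y³). Double-zeta (X = 2) rows are excluded
by default — they sit visibly off the X⁻³ trend. The raw HF/correlation
split for acetic acid lives in unpublished supplementary material, so
the MP2/CBS binding energy of −15.31 kcal/mol is treated as an *input*;
the extrapolation is nevertheless implemented generically (including a
correlation-component mode) for users with component-resolved tables.

The CCSD(T)/CBS composite adds the CCSD(T)−MP2 difference evaluated in a
common smaller basis to the MP2/CBS value, exploiting the near
basis-set-independence of that difference. Thermal corrections computed
at one level (MP2/triple-zeta) are pasted onto electronic energies as
ΔH = ΔE + (ΔH_MP2 − ΔE_MP2). For BSSE, adding *half* the counterpoise
estimate is provided as the recommended treatment: counterpoise
systematically overestimates the error, and the half-corrected value
empirically lands closest to the CBS limit. Table-comparison rounding is
round-half-even to two decimals, applied after composition. One known
caveat: the tabulated dispersion-corrected B3LYP ΔG° of −5.67 differs by
0.01 from recomputation at 298.15 K, indicating unrounded underlying
values; that row is excluded from exact checks.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis
assumes: exponential intensity decay with multiplicative Gaussian noise
(1 % relative), a constant baseline-pressure distortion (default
0.002 atm; recovery studies draw per-dataset offsets uniformly from
[0, 0.003] atm), and additive Gaussian shift noise (0.02 ppm, matching
the visible low-temperature scatter of the real data). The true pressure
is built from the *noiseless* intensity ratio through the same
baseline-corrected relation the fit inverts, so the true parameters have
zero expected residual and recovery bias isolates estimator properties.
Defaults are the experimental conditions: four temperatures
(25/60/80/100 °C), anchor pressures from the Antoine saturation pressure
at each temperature (0.021–0.56 atm), 800 points per dataset at one
spectrum per 150 s, decay constants giving a ~6-fold pressure drop at
25 °C and faster leaks when hotter (~(T_ref/T)² scaling — a convenience,
not a diffusion model).

Not emulated: the physics of diffusion through the FEP wall, exchange
broadening and the liquid+gas transition period, magnetic-susceptibility
offsets between gas and liquid signals, temperature-dependent noise, and
real baseline shapes. Passing recovery tests therefore demonstrates the
estimator is unbiased and well-calibrated *under the stated noise
model*, not that the experimental systematics are conquered; the glass
wall-adsorption bias term (Arrhenius-like, b₀·exp(−scale/T)) exists
precisely to show how a violated assumption surfaces as p0-dependent
estimates.

Randomness is seeded everywhere (mandatory seed, independent child
streams per dataset and per noise channel via `SeedSequence` spawning);
identical seeds give bit-identical datasets.

## Problem sizes

Recovery studies use 10 independently seeded four-dataset ensembles of
800 points each (32 000 fitted points per study) — comfortably inside
the 600–1200 points-per-dataset envelope of the real campaign and large
enough that replicate means of ΔH/ΔS/Δδ_D settle well inside the
experimental error bars. Unit tests use 150–600-point datasets and
reduced Monte Carlo iteration counts; the full 1000-iteration Monte
Carlo is exercised by the `analysis/02_global_fit.py` driver (~20 s).

## Known limitations

* Unweighted residuals; no robust-loss option for the low-temperature
  regime where a two-state model fits worst (the real data hint at
  entropically disfavored larger aggregates below ~25 °C).
* p_corr is constant per dataset; a drifting baseline would alias into
  it.
* The Antoine anchor is taken as exact within the Monte Carlo model —
  its own coefficient uncertainty is subsumed into the 10 % systematic.
* `fit_peaks` needs reasonable initial positions; there is no automatic
  peak picking.
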