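# Methods

## Kinetic model class

All reaction networks handled here are linear: every step is first order or
pseudo-first order. This matches the experimental regime the package
targets — O₂-saturated buffer and excess reductant fold the co-substrate
concentrations into the rate constants, and single-turnover conditions
(stoichiometric metal, no reductant) make each active site react once.
Consequences:

* the concentration vector obeys dc/dt = K·c with constant K, solved
  exactly by eigendecomposition of K (`scipy` dense matrix exponential per
  time point as fallback when K is defective, e.g. sequential steps with
  equal rates; the switch is a condition-number threshold of 1e8 on the
  eigenvector matrix);
* total amount is conserved to machine precision and concentrations stay
  non-negative up to roundoff;
* networks must be acyclic (checked by topological sort). Reversible steps,
  binding equilibria and second-order chemistry are out of scope.

Generic stiff integration (`solve_ivp`, LSODA, rtol 1e-12) is used only as
the independent oracle in the test suite, never in the library path.

The canonical internal time unit is minutes, because assay rate constants
are naturally min⁻¹; stopped-flow traces are stored in seconds and their
fitted rate constants reported in s⁻¹, with the unit carried explicitly on
every time course and fit report.

## Closed-form models and fitting

Product time courses are fitted to the exponential approach
P(t) = A0 − A·e^(−kt); stopped-flow transients to the two-channel
rise/common-decay model (each channel is a Bateman intermediate sharing the
decay constant k2). When |k2 − kᵢ|/kᵢ < 1e-6 the degenerate limit
ΔA·kᵢ·t·e^(−kᵢt) is evaluated instead, keeping the model continuous and
free of division by zero; the threshold is far below any resolvable rate
separation, so the switch is numerically invisible.

Fitting uses bounded least squares (lmfit/Levenberg–Marquardt) with
uniform weights — no heteroscedastic weighting, since replicate SDs of the
emulated assays are roughly uniform across the time grid. Initial guesses
are heuristic: plateau from the last point, rate from the half-rise time;
for transients, decay from the log-linear tail after the peak and rise
constants scaled to the peak time. Standard errors come from the fit
covariance; replicate scatter is summarized separately as the sample SD
over triplicates (n−1 denominator), and the two are deliberately not
merged. Non-convergence and unidentifiable parameters (no finite standard
error, e.g. a flat series leaving k free) are flagged on the result rather
than raised.

For the transient model the two formation channels are exchangeable; the
reported convention is k1 ≥ k1′. When the second amplitude is smaller than
twice its standard error, the nested single-channel model is refitted and
returned (flagged), preferring the fewer-parameter description.

Branch constants are computed as kᵢ = fᵢ·k_tot with fᵢ the amplitude
fraction of product i. This is the only reading consistent with parallel
first-order branches, where every product rises with the total rate
constant and the branching lives entirely in the amplitudes.

## Isotope-effect inference

The site map fixes which products report on which abstraction site:
desaturation, aziridine and C3-hydroxylation descend from C3–H
abstraction; C4-hydroxylation from C4–H abstraction; overoxidation
products fold into their precursor channel. Intrinsic KIEs follow from the
flux-ratio shifts (KIE_C3 = r_H/r_[3-D], KIE_C4 = r_[4-D6]/r_H); these are
exact under the branching model at zero noise because every step preceding
the branch point cancels in the ratio — the property the test suite
verifies over random parameter draws. The PCET KIE of desaturation uses
the aziridine channel as the reference (both descend from the same carbon
radical) and excludes the hydroxylation channel, which cancels as a common
factor.

The serial two-step model commits to the steady-state harmonic composition
1/k_app = 1/k_phys + 1/k_chem for an isotope-insensitive physical step in
series with the abstraction chemistry. The three observables (two apparent
rates and the protiated branching ratio) determine (k_phys, k_3H, k_4H) in
closed form; the solver reports infeasibility with a diagnostic when the
implied physical rate is non-positive or the KIEs are degenerate
(indistinguishable chemistry). KIE uncertainties, when requested, are
propagated by parametric bootstrap from replicate SDs (200 resamples,
fixed seed).

A consequence worth noting: the headline literature values for this system
do not close exactly under the harmonic model — abstraction constants of
3.5 and 1.1 min⁻¹ with intrinsic KIEs 25 and 36 and a protiated apparent
rate of 0.556 min⁻¹ imply a forward apparent KIE near 4.1, somewhat above
the 3.1–3.6 measured range, and a branching ratio of 3.18 versus 2.97 from
the printed branch constants. The inputs behind the published derivation
are not available at this level of detail, so the package treats round-trip
consistency (forward model → estimator → same parameters) as the testable
property and reports the serial-model forward values as such.

## Mössbauer model

Thin-absorber approximation: absorption is a plain sum of Lorentzians, no
transmission-integral saturation, so species fractions are simple area
fractions. A doublet is two equal-area lines at δ ± ΔE_Q/2 with common
FWHM Γ (default 0.30 mm/s, a typical ⁵⁷Fe linewidth; the weak applied
field's perturbation is ignored). Default grid ±6 mm/s at 0.01 mm/s. Note
that ~1–2% of a Γ = 0.30 Lorentzian's mass lies outside ±6 mm/s, so
integrals on the default window recover the truncated mass, not the full
area; the area parameter itself is defined analytically.

Decomposition fits up to three doublets by weighted least squares (1/sd
per point when SDs are present), with areas unbounded so difference
spectra (negative components) fit naturally; fractions are signed areas
over the summed absolute area. Initialization is either user-supplied
(e.g. reference parameters of known species — the recommended route for
strongly overlapping doublets, whose parameters are correlated and whose
best-fit basins are shallow) or automatic: line positions from peak
finding, paired nested (outermost pair = widest doublet), with moment-based
fallbacks, keeping the best of several starts. Near-degenerate parameter
pairs (|correlation| > 0.95) are reported on the fit result.

## Synthetic data

The generators emulate the study designs: an eight-point quench grid
(5 s, 10 s, 20 s, 30 s, 1, 2, 4, 10 min) in triplicate for single-turnover
assays; 1000 log-spaced points over 1000 s for stopped-flow; ±6 mm/s
velocity spectra with recorded SD bars for freeze-quench series. Noise is
additive Gaussian — 5% of each observable's dynamic range for time
courses, 1% of peak for traces, 2% of peak for spectra — chosen once as
defaults of the right visual magnitude for published error bars; real
instrument noise is likely heteroscedastic and these defaults make no
claim about it, which bounds what passing recovery tests show about real
data. All randomness flows from the single seed in `GeneratorConfig`
(sub-series use fixed offsets of it), so outputs are bit-reproducible.

The isotopologue generator implements the serial mechanism explicitly:
reactive complex → (physical step) → activated state → branch to C3/C4
abstraction, with the C3 radical partitioning rapidly (100 min⁻¹ overall,
fast against the serial steps so the partition is rate-ratio-determined)
into desaturation, aziridine and hydroxylation. Deuteration divides the
corresponding site's abstraction constant — and, for C4 deuteration, the
desaturation channel — by the intrinsic KIEs. Its default truth uses the
literature abstraction constants and KIEs with the physical-step rate
derived from the protiated apparent rate (0.633 min⁻¹); the initial
complex concentration (100 µM) sets only the amplitude scale.

The peroxo-accumulation scenario is parameterized, not reconstructed: the
intermediate's formation constant is not published, so the default scheme
places 60% of the iron in reactive complexes forming the intermediate at
2.0 min⁻¹ and decaying at the serial-model perdeuterated apparent rate
(≈0.134 min⁻¹), which peaks the intermediate at about half of total iron
near 90 s. It is a consistency illustration — the package's tests treat it
qualitatively (proper fraction, interior unimodal peak) and log the value
rather than asserting it.

## Known limitations

* First-order acyclic networks only; no binding equilibria, reversibility,
  temperature dependence or tunnelling-model corrections (Bell/Marcus).
* Uniform-weight fitting; no global multi-trace fits or Bayesian
  inference.
* Symmetric, equal-width doublets only; magnetically split spectra are out
  of scope.
* The coupling-efficiency ratio computed from the fully coupled generator
  is 1 by construction; detecting real uncoupling requires measured decay
  amplitudes, which the synthetic model does not attempt to invent.
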