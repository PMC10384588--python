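# Methods

## Spectra and conventions

The velocity autocorrelation spectrum (VAS) is defined as the one-sided
cosine transform of the velocity autocorrelation function,

    D(ω) = ½ ∫_{−∞}^{∞} ⟨v(t) v(0)⟩ e^{iωt} dt ,

so that D(0) is the long-time self-diffusion coefficient and, for a free
overdamped particle, D(ω) = kBT/γ at every frequency (the
Einstein–Smoluchowski value).  All formulas use angular frequency ω (rad/s)
internally; every container, file format and CLI flag carries ordinary
frequency in Hz, with the 2π conversion applied exactly once at that
boundary.  kB = 1.380649e-23 J/K (exact SI) is the single shared constant.

Spectra are one-dimensional throughout: the motivating measurement
(a spin-echo sequence with a magnetic-field gradient) observes displacement
along a single axis, and every simulator here is one-dimensional to match.

## Single-species solvent model

A molecule in a transient cage, harmonically coupled (constant k) to its
neighbours with friction γ and overdamped dynamics, has

    D(ω) = (kBT/γ) · (n + τc²ω²)/(n² + τc²ω²),  τc = γ/k .

Limits: D(0) = kBT/(nγ) (the whole cage must diffuse together) and
D(∞) = kBT/γ (free escape).  For n ≥ 1 the spectrum is non-decreasing, so
η(ω) ∝ 1/D(ω) falls with frequency: shear thinning, the pure-water
behaviour on the measurement band.

An exact structural identity pins down what "n coupled molecules" means:
this formula is *exactly* the per-particle VAS of a complete graph K_n of n
overdamped particles with uniform coupling k (verified against the network
oracle to machine precision in the tests).  Each molecule in K_n touches
n−1 literal neighbours; the model's n counts the molecules in the cage,
including the tagged one.

## Two-species (water + cluster) solvent model

Glycerol-rich mixtures are modelled by a star motif: a tagged overdamped
water coupled with the same constant k to n_w overdamped waters and n_c
heavy inertial clusters (mass M_c, no cluster–cluster springs), all sharing
the friction γ.  The cluster resonance ω₀ = √(k/M_c) parametrizes the mass.
The response matrix of the motif is an arrowhead matrix, so the tagged
water's spectrum has a scalar closed form:

    d_w = k − iωγ,  d_c = k − ω²M_c − iωγ,  d_0 = (n_w+n_c)k − iωγ
    Δ   = d_0 − n_w k²/d_w − n_c k²/d_c
    D(ω) = kBT γ ω² [1 + n_w k²/|d_w|² + n_c k²/|d_c|²] / |Δ|² .

This is the package's authoritative two-species spectrum; the printed
closed forms circulating for this model are typographically unreliable, so
the implementation is derived directly from the stated Langevin system and
verified against the brute-force network oracle to ~1e-15 relative (tested
at 1e-8).  ω = 0 is the analytic centre-of-mass limit
kBT/((1+n_w+n_c)γ).  With n_c = 0 the motif is a star of 1+n_w waters and
reduces *exactly* to the single-species model with n = n_w+1 — the count
includes the tagged molecule, consistent with the K_n identity above; a
reduction to n = n_w is impossible, since any connected (1+n_w)-particle
network with equal frictions has D(0) = kBT/((1+n_w)γ).

The correlation time of the mixture model is structurally τ = γ/k; a
constructor argument accepting τ exists but must agree with γ/k, because
the reconstructed system has no independent third timescale.

Cluster-dominated parameters make D(ω) monotone decreasing across the
50–3000 Hz band (thickening): the band then sits on the caged plateau
kBT/((1+n_w+n_c)γ) and descends into the cluster antiresonance near ω₀.

## Network oracle

For any linear network (masses M_i, possibly zero = overdamped; frictions
γ_i; symmetric PSD spring matrix K) driven by white thermal forces of
spectral density 2kBTγ_i,

    G(ω) = [K − ω² diag(M) − iω diag(Γ)]⁻¹
    D_i(ω) = ω² Re[G · 2kBT diag(Γ) · G†]_{ii} / 2 .

Overdamped particles are simply M = 0 in the same formalism.  At ω = 0 the
diffusivity is carried entirely by the free modes: D_i(0) = kBT/Σγ over the
particle's connected component if that component is translation invariant,
and 0 if it is pinned.  Dense linear algebra only (networks ≤ ~100
particles).  Validated invariants: non-negativity, permutation
equivariance, and the inertial equipartition sum rule
(2/π)∫ D_i dω = kBT/M_i (tested to 1%).

## Rouse chain with memory friction

The polymer is a free-ended chain of N Kuhn segments of length b with
entropic springs k = 3kBT/b² (the standard Gaussian-chain value; this makes
the segmental correlation time below consistent with γ/k up to the π² mode
factor).  With m retained modes the one-dimensional segmental VAS is

    D_R(ω) = Dc · [1 + Σ_{p=1}^{m} ω²τc²/((p/m)⁴ + ω²τc²)]
    Dc = kBT/(Nγ),  τc = b²γ/(3π²kBT) .

Bounds Dc ≤ D_R ≤ Dc(1+m) hold for all arguments; m defaults to N (long
chains).  A frequency-dependent solvent enters by replacing γ with
γ(ω) = kBT/D_solvent(ω) per evaluation frequency, making Dc and τc
frequency dependent.

**Integral closed form.**  The mode sum converts to an integral over the
continuous mode index.  The naive window u ∈ [0, 1] misrepresents the sum
by an O(1/m) endpoint term (≈4% at m = 100 for small ωτc); this package
integrates over the midpoint window [1/(2m), 1 + 1/(2m)], which equals the
sum to O(1/m²) (< 5e-6 relative at m = 100).  The antiderivative of
a²/(u⁴+a²) is evaluated analytically with an atan2-based branch-safe form;
an adaptive-quadrature fallback cross-checks it in the tests.  In the
regime 1/m² ≪ ωτc ≪ 1 the excess over Dc grows as
m·(π/2√2)·√(ωτc).

**Mode sum vs. the exact discrete chain.**  The (p/m)⁴ mode rates are the
long-wavelength approximation of the exact free-chain eigenvalues
4k sin²(pπ/2N); they agree for p ≪ N but diverge for the highest modes
(factor π²/4 in rate at p = m).  Comparisons between the mode-sum formula
and chain simulations are therefore restricted to ω ≲ 2k/γ, where the
approximation holds to a few percent.

**Extrapolation policy.**  A polymer band below the measured solvent band is
evaluated only through a fitted parametric solvent model; raw sampled
spectra are log-log interpolated inside their support and never
extrapolated (unstable and unjustified outside the data).

**Peak metrics.**  The most prominent interior maximum of a polymer
spectrum is reported with its frequency, full width at half prominence
(interpolated on the log-frequency grid) and the ratio of the peak to the
"plateau", defined as the mean spectrum over the top frequency decade.
Monotone spectra report no peak.

## Fitting

Both solvent models are fitted by bounded least squares on log-scale
residuals (log D model − log D data), matching the multiplicative noise
model of the measurement emulator; with reported uncertainties the
residuals are weighted by D/σ (delta method), otherwise unweighted
(constant relative error).  Parameters are optimized as logarithms
(positivity for free), from scale-free starting values — γ₀ = kBT/median D,
τ₀ = 1/(2π·geometric-mean frequency), ω₀-start at the steepest descending
log-log slope — with five deterministically jittered starts to escape the
mixture model's local minima (best rss wins; ties go to the smaller
parameter norm).  Neighbour counts are fixed small integers; the
single-species n is profiled over 1..6 when not fixed.  Covariances come
from the Gauss–Newton Hessian in log space, delta-transformed to linear
scale; AIC = n·ln(rss/n) + 2p selects between models, with ΔAIC < 2 — or
both fits numerically exact (rms weighted log residual < 1e-4), where AIC
differences are meaningless — reported as ambiguous.  A fitted mixture
resonance far outside the sampled band or with a standard error exceeding
the estimate itself is flagged `omega_o_unidentifiable` (the expected
outcome when thinning data is forced through the mixture model).

## Simulators and the measurement emulator

All study conditions are fixed in `vaspipe.presets` and reflect plausible
room-temperature values rather than any particular published fit (the
measured datasets and their fitted parameters are not published):

* water-like solvent: γ = 1.8e-12 kg/s (kBT/γ ≈ 2.3e-9 m²/s, the
  self-diffusion coefficient of water at 298 K), τc = 5e-4 s so the rise
  sits inside the band, n = 3;
* mixture-like solvent (33 vol% glycerol analog): γ = 4e-12 kg/s,
  τ = 2e-5 s, ω₀ = 2π·3000 rad/s, n_w = 2, n_c = 1 — monotone decreasing
  across the band by a factor ≈ 2.7;
* polymer: N = 5000 Kuhn segments, b = 5 nm — long enough that the mode
  spectrum responds inside the audio band; with these choices the
  mixture-immersed chain peaks near 2 kHz at ≈1.3× the high-frequency
  plateau.  Peak position and height depend on the (unpublished) solvent
  fit parameters; only the shape dichotomy — monotone rise in water,
  interior peak in the mixture — is treated as the reproducible feature.

**Network dynamics.**  Overdamped particles advance by Euler–Maruyama
(white-noise variance 2kBTγ·dt), inertial ones by a BAOAB splitting with an
exact Ornstein–Uhlenbeck velocity substep; the composed one-step affine map
is assembled once as a matrix, so the integrator loop is a single
matrix–vector product.  Initial positions are Gibbs-distributed in the
bound spring modes (free modes at the origin) and initial velocities at
equipartition, so runs are stationary from the first step.  The step-size
rule dt ≤ 0.01·min(γ/k, M/γ), with k the largest spring magnitude, is
enforced with a suggested dt in the error.

**Rouse dynamics.**  The chain is evolved in normal-mode space (modes
decouple because all beads share the kernel).  With white friction every
mode is an AR(1) recursion executed by a C-level linear filter, chunked in
time; this is bit-identical to bead-space Euler–Maruyama.  Memory kernels
use Markovian embedding: one auxiliary OU variable per Prony term per mode
carries both the retarded drag (−c·dx coupling) and its matching thermal
noise, so the fluctuation–dissipation relation ⟨f(t)f(0)⟩ = kBTγ(t) holds
by construction; the instantaneous response requires γ∞ > 0.

**Prony kernels.**  γ(t) = 2γ∞δ(t) + Σ c_i e^{−λ_i t} with c_i ≥ 0
(complete monotonicity ⇒ a positive friction spectrum).  Consequence worth
stating plainly: Re γ̂(ω) = γ∞ + Σ c_i λ_i/(λ_i²+ω²) is non-increasing in
ω, so completely monotone kernels can only *thin*.  `prony_fit` therefore
reproduces decreasing friction spectra (the water branch is exactly
one-term representable) but returns `ok=False` for rising (thickening)
targets — representing those requires oscillatory kernel components, which
are outside this kernel class and outside scope.

**Spectral estimation.**  Velocities by central differences, VAS by
averaged periodograms over non-overlapping rectangular segments (no taper —
adequate for smooth spectra), D = S_v/2, with the central-difference
transfer bias removed by cos²(ωdt/2) (exact for free diffusion).  The
cross-segment/particle standard error is reported per bin.  Raw periodogram
bins carry ~1/√(n_segments) relative noise, so comparisons against smooth
references use `log_bin_spectrum` (default comparisons: ~10 bins/decade),
the standard practice for periodogram-vs-model checks.

**Measurement emulator.**  `mgse_sample` draws log-spaced frequencies on
the 50–3000 Hz band (the hardware-limited window of the motivating
instrument) and applies i.i.d. multiplicative log-normal noise,
D_obs = D·exp(ε), ε ~ N(0, cv²), cv = 0.05 by default — a stand-in chosen
to mimic the visible scatter of such measurements; the true noise law of
the instrument is not published.  σ = cv·D_obs is reported.

## Problem sizes and numerical checks

The validation suite uses: 11e6 steps (dt = 2e-7 s) for the 4-particle
motif against the oracle, compared on log-binned estimates over the
100–1000 Hz decade (agreement ≤ 15%); 5e6 steps (dt = 8e-4, reduced units
kBT = γ = b = 1) for the N = 32 chain against the mode sum over
0.05–0.6 Hz (≤ 20%, the band where the continuum-mode approximation holds)
with the centre-of-mass diffusivity within 10% of kBT/(Nγ); 1e6 samples for
the colored-noise autocovariance against kBTγ(t) within 5% of the zero-lag
value for lags up to 3/λ_min (pointwise-relative error at long lags is not
statistically meaningful at this sample size); and 20 seeded replicates at
5% noise for parameter recovery (median errors: ≤ 10% water, ≤ 15%
mixture).  Trajectories may be stored float32 for long runs; statistics are
unaffected at the tolerances above and determinism is preserved.

## What the synthetic data does and does not show

The generator reproduces the *shapes* and noise character of band-limited
diffusion spectra, not any particular measured dataset: passing tests
demonstrate that the analysis chain is internally consistent (models ↔
oracle ↔ simulation ↔ fits) and recovers known generating parameters under
the stated noise, not that the preset parameters describe a real mixture.
Real spectra carry temperature dependence, possible non-Gaussian noise,
instrument baselines and composition-dependent cluster statistics, none of
which are modelled.  Known limitations: no hydrodynamic (Zimm) coupling, no
excluded volume or internal friction beyond the solvent kernel, no
temperature dependence, clusters do not interact with each other, and the
completely monotone kernel class cannot emulate thickening friction in the
time domain.
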