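# Methods

This note documents the models implemented in `fretdyn`, the choices made
where the design was genuinely open, what the synthetic-data generators do
and do not emulate, and the package's known limitations. Times are seconds
internally throughout; report layers convert to microseconds.

## Correlation models

### Separate (per-curve) model

Each auto- or cross-correlation is fit independently with

    G(τ) = (1/N) · T(τ) · D(τ),
    T(τ) = 1 + f/(1−f) · exp(−τ/τ_T),
    D(τ) = (1 + τ/τ_D)⁻¹ (1 + τ/(p²τ_D))^(−1/2),

the standard 3D-Gaussian-focus diffusion correlation times a triplet
blinking term. `N` is the mean molecule number in the effective focal
volume, `τ_D = μ²/4D` the lateral transit time, `p = z₀/μ` the axial/lateral
aspect ratio of the focus, and `(f, τ_T)` the triplet dark-state amplitude
and correlation time. Cross-correlations are fit with `f = 0`: triplet
flicker of one dye does not cross-correlate between spectrally separated
channels. In the reference workflow, `p`, `f` and `τ_T` are determined on
standard specimens (a free dye and a rigid double-labelled polyproline) and
then fixed — `fit()` accepts a `fix` mapping for exactly this.

The separate-fit report derives two comparison columns referenced to the
donor autocorrelation: `rel.N = N_x / N_ACd` and `Δτ_D = τ_D,x − τ_D,ACd`.

### Global (four-curve) model

The four curves AC-d, AC-a, CC-da, CC-ad are fit simultaneously with shared
`N`, `τ_D` and one intramolecular dynamics time constant `τ_I`:

    AC-d: (1/N) T(τ) D(τ; τ_D)     (1 + α e^{−τ/τ_I} + β)
    AC-a: (1/N) T(τ) D(τ; τ_D + Δ) (1 + γ e^{−τ/τ_I} + δ)
    CC:   (1/N)      D(τ; τ_D)     (1 − √(αγ) e^{−τ/τ_I} − √(βδ))

Two-state FRET interconversion with relaxation time `τ_r = 1/(k_open+k_close)`
modulates each channel's brightness; the induced fluctuation is positively
correlated within a channel (amplitudes `α`, `γ`) and anticorrelated between
channels with amplitude exactly `−√(αγ)` for ideal two-state switching —
the simulator reproduces this identity and the end-to-end tests rely on it.
`β` and `δ` are *static* contributions from FRET heterogeneity that
exchanges far more slowly than the transit time, i.e. effectively constant
multipliers over the lag window. `Δ` is a fixed transit-time correction for
the acceptor channel (different detection-volume chromatic offset), taken
from the separate fits rather than fitted.

**Why the cross-correlation static term is −√(βδ).** The assignment of the
static offsets to the cross-correlations is the one genuinely open reading
of this model family. Placing `+δ` (or any single static parameter that
also appears in an autocorrelation) in the CC multiplier creates an *exact*
scale degeneracy: the transformation `N → λN`, `α → λα`, `γ → λγ`,
`1+β → λ(1+β)`, `1+δ → λ(1+δ)` leaves all four curves unchanged, so the
shared amplitude `N` (and with it `α`, `β`, `γ`, `δ`) is structurally
unidentifiable. The symmetric form `−√(βδ)` follows the same
anticorrelation algebra as the dynamic term — slowly-exchanging FRET states
are anticorrelated between the channels just as fast-exchanging ones are —
and restores identifiability: the three amplitude observables
`(1+β)/N`, `(1+δ)/N`, `(1−√(βδ))/N` determine `N` uniquely
(`N = (u₁+u₂−2u₅)/(u₁u₂−u₅²)`). Noise-free round trips recover all
parameters to machine precision from widely jittered starts; this was
verified numerically before adoption. The functional forms are isolated in
`eval_separate` / `eval_global`, so an alternative reading is a
one-function swap.

### Fitting

Both fits use bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`, numerical Jacobian, `xtol=ftol=gtol=1e-15`)
with a multi-start strategy: the supplied init plus five per-parameter
multiplicatively jittered starts (factors uniform in [0.5, 2], seeded), best
residual wins. Multi-start guards against the time constants
(`τ_I`/`τ_T`/`τ_D`) exchanging roles from a bad basin. Default bounds:
`τ_I ∈ [1 µs, 10 ms]`, `f` and all scale/static terms in `[0, 1]`,
`τ_D ∈ [1 µs, 0.1 s]`. `Δ`, `f`, `τ_T` and `p` are fixed at their init
values by default (the reference-measurement workflow); pass `fix` to
change the fixed set.

Standard errors come from the SVD pseudo-inverse of `JᵀJ` scaled by the
residual variance; directions in the numerical null space, and parameters
whose Jacobian column carries (almost) no gradient, are reported as
infinite rather than spuriously small. `τ_I` is flagged unidentifiable
when its standard error exceeds its estimate — which happens, as it
should, when the fitted dynamic amplitudes vanish (the lipid-locked
condition).

Default weights are `√n_samples` per point (σ ∝ 1/√averaging-count) for
measured multi-tau curves and unit weights for synthesized curves; explicit
per-curve weights override both. When the noise model is known (as in the
noise round-trip validation), inverse-σ weights give the proper GLS
estimator; under 2% relative per-point noise at apo-like parameters the
median relative `τ_I` error is ~9% (200 seeds) — the apo acceptor dynamic
amplitude `γ ≈ 10⁻⁴` contributes essentially nothing, so `τ_I` rides almost
entirely on the donor-autocorrelation bump and is intrinsically the
least-determined parameter, consistent with its large quoted uncertainty.

## Photon-stream simulation

Molecules perform Brownian dynamics in a periodic box around a 3D Gaussian
detection profile `W(r) = exp(−2(x²+y²)/μ² − 2z²/z₀²)`, `z₀ = pμ`. Only
the positions are discretized (Brownian increments are exact at any step,
default 5 µs ≈ τ_D/45); the two telegraph processes — conformational
switching at `k_open`/`k_close` and triplet blinking with stationary dark
fraction `f` and correlation time `τ_T` — are sampled with exact
exponential dwell times, and photons are emitted from the
piecewise-constant-rate segments between telegraph events with exact
uniform arrival times. Microsecond triplet kinetics are therefore
reproduced faithfully at a multi-microsecond position step; the dwell-time
distributions are verified exponential by Kolmogorov–Smirnov tests.
Crosstalk reroutes each donor photon to the acceptor channel with
probability β; background photons are Poisson-added per channel.

Defaults emulate the apo measurement: `μ = 0.25 µm`, `D = 70 µm²/s`
(`τ_D = 223 µs`, the scale of the measured transit time), `p = 3`,
per-molecule peak brightness 40/10 kcps with the closed state bright in the
acceptor channel and the open state bright in the donor channel (the FRET
contrast that produces AC amplitudes ~0.4 and the CC dip), switching rates
2250/2750 s⁻¹ (the ~200 µs relaxation at 55/45 closed/open), and the
reference triplet `f = 0.28`, `τ_T = 3.8 µs`.

**The periodic box and its artefacts.** The box (default half-widths
3.5 μ laterally, 2.2 z₀ axially, with 40 molecules ≈ 1 molecule in the
focus) keeps the molecule number fixed; the detection profile is < 10⁻⁸
(lateral) / 4×10⁻⁴ (axial) of its peak at the boundary. Two exact
consequences, both reproduced by the simulation and captured by the
finite-box oracle used in the tests (per-axis Fourier-mode sums of the
wrapped diffusion propagator): the amplitude sits a factor `1 − N_eff/n`
(~2.6%) below the open-volume value, and the algebraic diffusion tail is
cut off beyond the slowest periodic mode (~1 ms at the default box) —
molecules cannot wander arbitrarily far. Correlation-curve fits that
weight the decades around `τ_D` are barely affected (the end-to-end
relaxation-time recovery lands within a few percent); fitted `τ_D` comes
out a few percent low, and a free `p` soaks up tail distortion, which is
one more reason `p` is fixed from references. Enlarging the box suppresses
the artefacts at linear cost in molecules.

## Binned-trajectory simulation

Each trajectory is one immobilized molecule: bleach time exponential
(mean 8.8 s), 100 ms bins, then background-only bins after the bleach so
that change-point detection is exercised. Latent per-bin distances (R₀
units) follow the regime:

- **static** — the state (closed/open, drawn from the configured weights)
  and the molecule's own mean distance are drawn once per trajectory; bins
  scatter around that value with a small within-state spread (default
  0.03 R₀, conformational breathing), while the molecule-to-molecule spread
  makes up the rest of the state's marginal sd (default 0.08 R₀ total).
  Splitting the width this way is what makes the per-molecule histograms of
  a locked cohort unimodal, as observed: a molecule near the decision
  boundary scatters tightly around *one* value instead of straddling both
  peaks.
- **switching** — an exact two-state telegraph runs through the trajectory
  and each bin receives the occupancy-weighted mixture of fresh per-state
  draws. With relaxation far below the bin width every bin collapses onto
  the population-weighted mean (the fast-exchange limit smFRET cannot
  resolve); with dwells longer than bins, single trajectories visit both
  peaks. The config enforces that the state weights equal the equilibrium
  populations implied by the rates.

Distances map to efficiencies via `E = 1/(1+R⁶)` (R in R₀ units); detected
counts are `I_D ~ Poisson((1−E)Λ/γ)` and `I_A ~ Poisson(EΛ + β I_D-rate)`
with Λ = 500 photons/bin, β = 0.08, γ = 1.1 by default, plus ~2 background
counts/bin — so the efficiency corrections are genuinely exercised and
invert the distortions in expectation. Cohort sizes default to the
experimental 26 (apo) / 28 (lipid) trajectories; the per-bin photon budget
and peak widths are not reported for the original experiment and are
documented package choices (chosen so the apo peaks are cleanly resolved
and the per-bin distance noise from photon statistics stays well below the
peak widths).

## smFRET analysis

Efficiencies use the crosstalk-then-γ ratiometric correction; bins with no
signal are dropped and logged. Distances are kept in R₀ units, with Å
conversion through the Förster radius (51 Å) only at I/O. Bleach detection
looks for one-bin drops of total intensity larger than 5 robust (MAD)
scales of the bin-to-bin differences, sustained to the trace end below 35%
of the pre-step level; the *first* such step terminates the analysed
window, so acceptor-then-donor double bleaches stop at the first event.

The pooled distance distribution is decomposed by bounded least squares of
a two-Gaussian mixture against the histogram density (bin width 0.025 R₀)
— the figure-style workflow — with multi-start over several quantile-pair
inits so a minor component hiding in one tail is found; a sample-level EM
fit (`scikit-learn` GaussianMixture) is provided as an independent
cross-check. Component widths are bounded above (default 0.15 R₀): a
component much broader than a state peak is an envelope sweeping up the
other state's mass rather than a conformation, and peaks that broad could
not be resolved as two states at the separations involved — without the
bound, about a third of small overlapping cohorts converge to such envelope
solutions and bias the recovered weights. Components are reported in
ascending-mean order (closed = smaller distance); fits whose separation is
below twice the larger sd are flagged unresolved.

Classification assigns each bin by posterior probability under the fitted
pair; a bin counts as a *confident* visit above posterior 0.8, and a
trajectory is labelled `both` only if each component collects ≥ 3 confident
visits **and** the two visited groups are genuinely bimodal (their mean
distances differ by at least half the component separation). The
bimodality guard distinguishes a switching molecule (bins at both component
means) from a static molecule whose own distance happens to sit near the
decision boundary; against the generator's latent states the classifier
agrees > 99% of the time, and locked cohorts produce zero `both` labels
whenever the decomposition itself is resolved. At study-scale cohorts
(26–28 molecules) the recovered closed fraction tracks the *realized*
cohort composition to < 4 points median; deviations from the nominal
generator weight are dominated by the binomial sampling of so few
molecules (~8 points median), which is why population figures are reported
as medians over many seeded cohorts.

## Kinetics

`τ_r = 1/(k_open+k_close)`, `P_open = k_open τ_r`; conversions in both
directions are exact algebra. The fitted FCCS `τ_I` is identified with
`τ_r` — the looser "time shift between AC and CC" language maps onto this
single definition. With the apo populations (45% open) and a 200 µs
relaxation this gives `k_open = 2250 s⁻¹`, `k_close = 2750 s⁻¹` (derived
values; the combination, not the individual rates, is what each experiment
measures).

## Multi-tau correlator

Photons are binned at a base resolution (default 1 µs); level 0 correlates
at lags 1..16 base bins, every further level halves the time resolution by
pairwise bin summation and correlates at lags 9..16 coarse bins (16 points
per level, 20 levels ≈ 1 µs–8 s). Normalization is the symmetric
fluctuation form `G = M Σa_i b_{i+k} / (Σa_i Σb_{i+k}) − 1` with all sums
over the M overlapping samples at that lag, so `G(∞) → 0` and the
finite-duration bias cancels to leading order; a trailing partial bin is
dropped at every resolution, which makes the multi-tau output *exactly*
equal to the brute-force estimator computed at each level's bin width (the
in-repo oracle). Amplitudes `1/N` are preserved under this convention, so
fitted `N` is comparable across tools. Lags beyond a quarter of the stream
duration are truncated with a warning. Curve smoothing averages adjacent
lags weighted by sample counts, combining lags by geometric mean.

## Problem sizes

The validation suite and the reproduction script run on one CPU: global
and separate round trips use 200 log-spaced lags (seconds); population
recovery uses 101 cohorts of 26–28 trajectories per condition
(median-reported); the end-to-end relaxation-time recovery simulates five
60 s photon streams of 40 molecules (~10⁶ photons each, ~2 minutes per
stream; the test suite runs a single 30 s stream). These sizes were chosen
to keep each stochastic estimate's uncertainty well inside the quantity's
own variability; all are configuration parameters.

## Limitations

- No polarization, detector afterpulsing/dead time, or spectral
  bleed-through beyond a single crosstalk coefficient; one triplet state
  only.
- The periodic simulation box truncates the long-lag diffusion tail
  (above); amplitudes carry the fixed-N correction.
- The two-Gaussian decomposition of a 26–28-molecule cohort is ill-posed
  whenever the minor state is represented by only one or two molecules
  drawn near the major peak; such fits are flagged unresolved rather than
  prevented.
- No hidden-Markov dwell analysis of the binned trajectories: with a
  ~200 µs relaxation and 100 ms bins, individual dwells are unresolvable
  by construction, and the bin-level generator reflects that.
- The global model assumes one diffusing species and state-independent
  diffusion; multi-component diffusion and Bayesian uncertainty
  quantification are out of scope.
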