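# Methods

This note documents the models, algorithms and numerical choices behind
`selstop`, and what its synthetic-data tests do and do not establish.

## The task

A response-selective stop-signal task: every trial demands a bimanual button
press to a dual go stimulus (DS, deadline 1100 ms after go onset, foreperiod
uniform on [500, 700] ms). On one third of trials a selective stop signal
follows after the stop-signal delay (SSD): a left stimulus (LS) means "stop
the right hand, keep pressing left", a right stimulus (RS) the reverse.
Conditions differ only in advance information: *reactive* blocks give no cue;
*proactive* blocks cue which hand may have to stop, congruently with any stop
signal that follows. A 576-trial condition contains 384 DS, 96 LS and 96 RS
trials.

SSD is tracked per (condition, stop side) by a 1-up/1-down staircase in
50 ms steps from 200 ms, clamped to [0, deadline − 100] ms. The staircase
steps SSD **up after a successful stop and down after a failed stop**. This
is the only self-correcting direction: stop success falls as SSD grows, so
the tracker equilibrates where P(success) = 0.5 (the classic 1-up/1-down
fixed point, verified to 50% ± 2% over thousands of simulated trials, with
equilibrium SSDs in the 240–290 ms range). The opposite assignment is a
positive feedback loop that pins SSD at the floor and drives success above
85%, which contradicts the tracking goal and the observed behaviour of such
staircases; we therefore regard the direction as fixed by the fixed-point
property rather than by convention.

## The SIS race model

Each trial is a race among up to three independent "runners" with
ex-Gaussian finish-time distributions (Normal(μ, σ) + Exponential(τ); the
running-time summary is the mean μ + τ):

* **dual-go** — starts at the go stimulus; produces the bimanual response.
* **dual-stop** — starts at the stop signal (SSD); if it finishes before the
  dual-go runner, the bimanual response is cancelled.
* **selective (unimanual) go** — starts *simultaneously* with the dual-stop
  runner at the stop signal; produces the continuing hand's response at
  SSD + its finish time. "Simultaneously inhibit and start": stopping and
  reprogramming are concurrent, not serial.

Three probabilities capture rare events: `gf` (the go process never
launches), `tf` (the stop signal goes unprocessed — neither stop-triggered
runner launches), and `eps_wrong` (the wrong hand's selective runner is
launched). All are sampled on the probit scale in the hierarchical model.
Responses later than the deadline are recorded as no-response (NR); response
mass beyond the deadline is assigned to NR without renormalizing observed-RT
densities. Unimanual responses to a dual stimulus are not modelled
mechanistically; they are absorbed by the per-trial likelihood floor
`p_floor = 1e-10`, which also guards every likelihood term against underflow.

### Likelihood

For a stop trial at delay *d* with deadline *T*, writing f/S for density and
survivor of dual-go (G), dual-stop (S), correct-hand selective (U) and
wrong-hand selective (W):

* failed stop (DR at t): (1−gf)·f_G(t)·[tf + (1−tf)·S_S(t−d)]
* correct unimanual at t: (1−tf)(1−eps)·f_U(t−d)·[gf + (1−gf)·P_win(d)]
* wrong-hand unimanual at t: as above with eps·f_W(t−d)
* NR: the structural sum of never-launched and past-deadline paths.

P_win(d) = P(d + T_S < T_G) is evaluated in closed form: T_G − T_S is a
Normal plus an asymmetric-Laplace variable (difference of two exponentials),
giving

P_win(d) = w_G·S_exG(c; 0, s, τ_G) + (1−w_G)·F_exG(−c; 0, s, τ_S),

with c = d − (μ_G − μ_S), s = √(σ_G²+σ_S²), w_G = τ_G/(τ_G+τ_S). The closed
form replaces adaptive quadrature in the sampler's inner loop (~10⁶
evaluations per fit); an adaptive-quadrature route is retained as
`stop_win_probability(..., method="quad")` and the two agree to <1e-5 in
tests, alongside a Monte-Carlo cross-check. The one remaining integral, the
probability that the go runner both beats the stop runner and the deadline,
is smooth and handled by fixed 32-node Gauss–Legendre quadrature per unique
SSD. Category probabilities from the likelihood agree with simulator
frequencies at n = 10⁵ within 3 binomial SEs across parameter regimes, and
sum to 1 within 1e-4.

Ex-Gaussian density/survivor use the scaled complementary error function
(`erfcx`) with a pure-exponential tail branch, stable over the whole support;
they match `scipy.stats.exponnorm` to ~1e-16 and are vectorized for the
sampler.

## Hierarchical Bayesian estimation

Independent truncated-Normal population distributions per parameter
(location + scale), no cross-parameter correlation. Supports: μ ∈ (0, 2000),
σ ∈ (1, 500), τ ∈ (1, 1000) ms; probits ∈ (−6, 6). Weakly informative
hyperpriors: location priors N(400, 200) for μ, N(50, 50) for σ, N(100, 100)
for τ, N(−1.5, 1) for probits (each truncated to the support); half-width
truncated-Normal priors on the group scales. These cover the plausible range
of human latencies with wide mass.

Model variants toggle, per runner, whether its parameters differ by
condition: variant 1 (dual-go and both selective runners vary, dual-stop
shared), 3 (as 1 but dual-go shared), 4 (as 1 but selective runners shared),
5 (all vary). Variant 2 is deliberately absent; the ids keep the original
analysis's numbering.

### Sampler

Two stages: each participant is first fitted alone (data-informed start
points, short DE-MCMC under the location hyperprior), and those chains seed
the hierarchical run. The hierarchical sampler is a blocked Gibbs scheme
over chains C = 3k (k = per-subject parameter count):

* **Subject blocks** — per subject: one full-vector DE crossover
  (γ = 2.38/√2k, 10% γ = 1 mode jumps, ±1e-3 jitter), a sweep of 3-D
  crossovers over every runner's (μ, σ, τ) triplet and the probit triplet
  (full-vector acceptance in 24 dimensions is ~8%, triplets ~25%), a 4-D
  block joining the dual-stop triplet with tf (a failed stop can reflect a
  slow stop runner *or* an unprocessed stop signal, and chains must slide
  along that trade-off), ridge moves that hold a runner's mean μ+τ and
  variance σ²+τ² fixed while moving τ along the weakly identified (σ, τ)
  fiber (with the 1/(2σ) Jacobian of the (M, V, τ) chart), and
  population-resample moves that redraw one coordinate from the group
  distribution (the population density cancels against the proposal, so
  acceptance is the bare likelihood ratio — this keeps near-likelihood-free
  coordinates such as `eps_wrong` from collapsing across chains).
* **Group blocks** — the conditional posterior factorizes across parameters
  given the subject draws, so every (location, scale) pair updates in one
  vectorized 2-D DE crossover, plus a conditionally-scaled random-walk
  refresh and a hyperprior independence move. This group sampler was
  validated against 2-D grid integration of the exact conditional.
* **Funnel moves** — joint rescale (scale′ = c·scale, deviations scaled by
  c, Jacobian c^(S+1)) and joint translate (location and all subject values
  shifted together) per parameter, with step-size mixtures. Plain
  conditional updates leave group scale and subject spread locked together;
  these moves are what lets the hierarchy breathe.
* Optional migration (cyclic state exchange among a random 10% of chains)
  during burn-in.

### Convergence rule and its limits

Sampling runs until the split-R̂ of the *monitored quantities* — group-
location running times μ+τ per runner cell, probit locations, and
subject-mean running times — falls below 1.10 (window 200 iterations,
checked every 100), after which a fixed window (default 250 iterations per
chain) is retained for all analyses. Failure to converge within
`max_iterations` raises `ConvergenceError` with the R̂ table.

Known limitation: the group *scale* hyperparameters of σ and τ components
sit in a hierarchical funnel on top of the ex-Gaussian (σ, τ) ridge and mix
roughly an order of magnitude more slowly than the monitored quantities.
They are excluded from the stopping rule — no reported quantity (running
times, contrasts, BPIC, posterior predictions) depends on them — but
`convergence_diagnostics` reports split-R̂ and ESS for every stored
parameter, so their state is always visible. Treat posterior summaries of
those scales as exploratory.

### Model comparison and contrasts

BPIC = D̄ + 2·p_D with D̄ the posterior mean deviance and p_D = D̄ − D(θ̄)
at the posterior-mean subject parameters; lower is better; a negative p_D
triggers a warning (possible multimodality) but the value is returned.
Contrasts are computed draw-wise on the running-time (μ+τ) scale from
subject-level parameters averaged across subjects, then summarized by the
median and central 95% interval — the "individual-level estimates"
convention. Contrasting a runner across conditions under a variant that
shares it raises an error rather than returning a structural zero.

## CancelTime censoring simulation

A partial EMG burst is physically detectable only when the stop runner beats
the go runner by a margin inside a window: at least 90 ms (50 ms partial
peak-to-offset + 20 ms minimum offset-to-onset separation + 20 ms RT-burst
onset-to-press), at most 115 ms (a larger margin cancels the response before
any muscle activity arises). `censoring_bias_sim` simulates stop trials
through the staircase, compares the mean stop-runner finish over all
successful stops against the margin-censored subset, and reports the bias
and censored fraction. With the package's default study parameters the
censored subset is ~10–13% of successful stops and the bias is negative
(down-bias) in both conditions — the selection artifact that makes
CancelTime look faster than the underlying stopping process.

## EMG pipeline

Conditioning: 4th-order Butterworth band-pass 20–500 Hz, applied
forward-backward (zero phase, so onsets are not delayed); envelopes are
full-wave rectified signals low-passed at 10 Hz (zero phase, clipped at 0).

Burst detection (single-threshold): the quietest 500 ms segment (sliding
RMS, 1-sample stride, earliest tie) defines baseline; threshold = rectified-
baseline mean + 3 SD. The rectified signal is smoothed with a 5 ms moving
average before thresholding — a raw rectified wide-band signal crosses zero
every few samples, so literal supra-threshold runs fragment real bursts
while isolated noise spikes merge into spurious ones; the short smoothing
window is the standard single-threshold remedy and sets the effective onset
resolution (~2–4 ms late bias, well under the 5 ms validation bound).
Supra-threshold runs separated by <20 ms are merged (idempotent,
order-independent), then merged bursts shorter than 10 ms are discarded.
Detection is invariant to positive rescaling. Burst peaks (time and
amplitude) are read from the envelope within the raw-threshold onset/offset
span.

Classification per trial: the RT-generating burst is the *last* burst with
onset after the go signal and at least 50 ms before the press. On successful
stop trials only, the partial (cancelled) burst is the *earliest* burst in
either hand satisfying all four constraints: onset after go, envelope peak
after the stop signal, peak before the responding hand's RT-burst onset, and
peak amplitude above 10% of the participant's mean successful-bi-go envelope
peak (normalization reference, taken from the reactive condition).
CancelTime = partial peak − stop-signal time. Profile averaging aligns
normalized envelopes to go / stop / EMG onset / peak, averages within then
across participants, with pointwise t-based 95% CIs.

## Synthetic data generator

`sample_group` draws subject-level SIS parameters from truncated-Normal
populations. Defaults encode the study conditions: dual-go running time
451 ms reactive / 481 ms proactive (+30 ms proactive slowing), selective
runners 316 / 289 ms, condition-invariant dual-stop runner at 175 ms,
between-subject SDs (30, 8, 12) ms for (μ, σ, τ), gf ≈ 2%, tf ≈ 5%,
eps ≈ 1%. `generate_behaviour` runs the full trial-by-trial design with live
staircases and keeps the latent race outcomes; bimanual presses get a left-
right asynchrony with SD 25 ms, putting ~4–5% of bimanual trials beyond the
50 ms simultaneity cutoff that `clean_bimanual` enforces (strict
inequalities throughout: exactly 25% stop success is retained, exactly 50 ms
asynchrony is kept, exactly 100 ms relative RT is not flagged).

`synth_emg` turns a trial's latents into two-channel raw EMG at 2000 Hz:
Gaussian baseline noise (SD 0.01 mV); bursts are band-limited (20–500 Hz)
noise carriers under raised-cosine windows. RT-generating bursts start
60 ms before each press (electromechanical offset; keeps planted bursts
detectable under the 50 ms rule), rise in 6 ms, sustain ~110 ms. Partial
bursts (rise 50 ms, decay 50 ms) are planted on successful stops whose
margin lies inside the censoring window, peaking at SSD + stop finish; the
generator centres each burst so its noise-free envelope peak lands exactly
on target, because the carrier's own envelope fluctuation would otherwise
displace the peak by ~5–10 ms and make the planted "truth" unrecoverable in
principle. The stopping hand always receives the partial; the responding
hand receives a copy only when its offset precedes the RT-burst onset by at
least the 20 ms separability limit (otherwise the two bursts physically
merge). An optional `mirror_rate` plants spurious bursts peaking after the
RT-burst onset for stress-testing the rejection constraints. Seeds split
hierarchically (cohort / subject / trial) so any trial is independently
reproducible.

What the synthetic data do *not* emulate: motor-unit physiology, tonic
pre-stimulus activity, electrode artifacts, amplitude variability of real
partial bursts, or sequential effects beyond the staircase. Passing the
round-trip tests shows the pipeline recovers what the generator planted
under its noise model — it bounds algorithmic error, not biological
validity.

## Validation scale

The test suite runs everything at desk scale, as the package's own choice of
problem sizes: staircase fixed point over 5,000 stop trials; likelihood vs.
simulation at n = 10⁵ per setting; parameter recovery with 8 subjects × 288
trials/condition (group-level 95% CIs cover every runner's generating μ+τ
and the realized cohort-mean slowing contrast, whose estimand is the +30 ms
hyper-mean plus between-subject sampling variation); BPIC selection
consistency over 3 replicate datasets of 4 subjects × 72 trials/condition
with a relaxed monitored-R̂ threshold of 1.15 (variant 1 vs 5);
censoring bias at 60,000 stop trials/condition; EMG round trip over ~120
successful-stop traces plus noise-only and mirror stress sets (RT-onset mean
absolute error ≤ 5 ms, CancelTime mean absolute error ≤ 5 ms, zero false
bursts, 100% mirror rejection).
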