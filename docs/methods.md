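# Methods

## The generative model

Each response channel is a rise-to-threshold ("LATER"-style) decision unit.
On every trial a decision signal starts at level `S0`, rises linearly at a
rate `r` drawn once per trial from `N(mu_r, sigma_r^2)`, and triggers the
response on reaching the threshold `ST`. Writing `Delta = ST - S0` for the
threshold interval, the latency is `Delta / r`, so *promptness* (reciprocal
latency) is Gaussian with mean `m = mu_r / Delta` and SD `s = sigma_r /
Delta` — the *recinormal* distribution. On a reciprobit plot (cumulative
probability on a probit scale against latency on a reciprocal scale) a
recinormal sample lies on a straight line whose value at infinite time is
`-m/s` probit units.

Two algebraic identities carry all downstream inference:

* changing `Delta` rescales `m` and `s` by the same factor, so the
  reciprobit line **swivels** about its infinite-time intercept;
* changing `mu_r` (the gain) moves `m` alone, so the line **shifts**
  laterally with unchanged slope.

Rates drawn at or below zero never reach threshold; the latency
distribution is therefore defective with response probability
`Phi(m/s) < 1`. The package keeps the CDF unconditional (its supremum is
the response probability), exposes the miss probability separately, and
raises an explicit error for quantiles inside the defective mass. In
simulated data such trials are recorded as *censored*, alongside trials
slower than the response window, so fitters always know the number of
attempts.

## TIMER/RIDER modulation

Two attentional modulators regulate every decision unit through one global
inhibition process `I`:

* **TIMER** (signal `T` in `[T0, T1]`) narrows the threshold interval:
  `Delta_eff = Delta * (1 - c_t * normT)` with `normT = (T-T0)/(T1-T0)`;
* **RIDER** (signal `R` in `[R0, R1]`) boosts the gain:
  `mu_eff = mu_r * (1 + c_r * normR)`.

The effects are independent and additive — each touches its own parameter
only, and the rate SD is never modulated — so TIMER engagement produces an
exact swivel and RIDER engagement an exact shift, by construction.
Inhibition mirrors the modulators linearly and inversely,
`I = I1 - (I1-I0) * (w_t*normT + w_r*normR)` clamped to `[I0, I1]`, and an
all-or-nothing express bypass opens when `I <= theta_express` (inclusive
boundary, a documented convention). State dynamics are deterministic Euler
updates: each modulator integrates its external drive plus a feedback
increment (`feedback_gain` per executed movement), clamped to its bounds.

The mapping from modulator levels to unit parameters has no prescribed
functional form in the underlying theory; linear fractional scaling with
caps `c_t in [0,1)` and `c_r >= 0` is the minimal choice that preserves the
exact swivel/shift signatures. Likewise `theta_express`, `feedback_gain`
and the drive schedule are free parameters with documented defaults, not
theory-derived values. The defaults are chosen so that a single-modulator
boost saturates its signal (halving inhibition) without opening the express
gate, while joint engagement — e.g. movement feedback, which increments
both T and R — reaches full release and opens it. The early unit's slope
`sigma_prime` is deliberately not modulated: the early line is
parameterized directly in promptness, and the theory gives no coupling for
it (a flagged model-fidelity gap; its mixture weight is likewise a free
parameter rather than a function of state).

## Default study conditions

| parameter | default | meaning |
|---|---|---|
| `S0, ST` | 0, 1 | unit threshold interval (arbitrary activation units) |
| `mu_r, sigma_r` | 5, 1 /s | promptness N(5, 1); median latency 200 ms |
| `c_t, c_r` | 0.3, 0.3 | full TIMER: `Delta x 0.7`; full RIDER: gain `x 1.3` |
| `w_t, w_r` | 0.5, 0.5 | equal inhibition coupling |
| `theta_express` | 0.05 | gate opens only near full release |
| `feedback_gain` | 0.05 | per-movement increment to T and R |
| schedule | 20 steps, drive 1.0, dt 0.1, 2 movements/step | saturates the driven signal |
| early component | `sigma_prime` 2 /s, weight 0.05 | occasional early responses |
| express band | truncated normal on [80, 134] ms, mean 100, SD 10 | human floor 80 ms; monkey preset 60 ms |
| `p_express` | 0.8 | per-trial express probability while the gate is open |
| response window | 1000 ms | trials beyond it are censored |
| latency classes | [80,135), [135,180), [180,400), [400,inf) ms | express / fast regular / slow regular / late; below 80 ms anticipatory |

The printed class boundaries (80–134, 135–179, 180–399, over 400 ms) are
realized as half-open intervals so every printed integer keeps its class
and non-integer latencies in the 1 ms gaps are still classified. Latencies
are carried in seconds internally and milliseconds at every file boundary.

## Simulation procedure

Per trial: while the express gate is open, an express latency is emitted
with probability `p_express`, drawn from the truncated normal band (the
truncation guarantees the floor); otherwise the trial is early with
probability `early.weight` (promptness from `N(0, sigma_prime^2)`) and main
otherwise (rate from the modulated unit). All random draws for a dataset
come from one `numpy` Generator in a fixed order (assignment uniforms, then
full-length candidate vectors selected by mask), so identical
(config, state, seed) yields a byte-identical dataset. The two-condition
experiment uses seeds `seed` and `seed + 1` for pre and post.

## Fitting

* **Single recinormal fit** — with no censoring the ML estimate of `(m, s)`
  is exactly the sample mean and population SD of promptness; with
  censoring, an optional right-censored likelihood adds a
  `log Phi((1/w - m)/s)` term per censored trial (absorbing both slow and
  never-responding trials) and is maximized by Nelder–Mead from the moment
  start. Reported log-likelihoods are on the latency scale (they include
  the reciprocal-transform Jacobian, constant across nested hypotheses).
* **Early mixture** — EM on promptness for `pi * N(0, sigma_prime^2) +
  (1-pi) * N(m, s^2)` from a deterministic start (moments; `sigma_prime =
  3 s`; `pi = 0.1`), tolerance 1e-8, at most 500 iterations. Because
  roughly half the zero-mean early mass has non-positive promptness and
  censors, the fitted weight estimates the early fraction *among observed
  responses*, not the attempt-level weight. If EM ends below the nested
  single-component optimum, the `pi = 0` boundary solution is returned
  (flagged), so the mixture likelihood never undercuts the single fit.
* **Reciprobit coordinates** — plotting positions `k/(n+1)` by default,
  Blom's rule optionally; the x coordinate is promptness itself (reversing
  the axis is a rendering concern, which keeps fitted signs unambiguous).

## The swivel/shift comparison

Four nested hypotheses on the two conditions' promptness samples:

| hypothesis | constraint | free parameters | fit |
|---|---|---|---|
| same | one line | 2 | pooled moments |
| swivel | common intercept `k = m/s` | 3 | profile likelihood over `k` |
| shift | common slope `s` | 3 | per-condition means, pooled ML variance |
| full | none | 4 | per-condition moments |

Under the common-intercept constraint the per-condition scale given `k`
solves the quadratic `n s^2 + k B s - A = 0` (`B = sum p`, `A = sum p^2`)
in closed form, leaving a one-dimensional bounded search over `k`; the
moment-ratio candidates are also evaluated so the nested log-likelihood
ordering holds exactly. Verdict logic: test *same* against *full* (LR,
chi-square, 2 df); if not rejected the verdict is **none**; otherwise test
*swivel* and *shift* each against *full* (1 df) and return the surviving
constrained model with the higher log-likelihood, or **full** if both are
rejected. By default the two planned second-stage tests run at the nominal
alpha; `correction="bonferroni"` halves it for family-wise control, which
the multi-replicate verdict studies use so the probability of
mis-labelling a true swivel/shift stays at `alpha/2` jointly.

## Problem sizes and numerical choices

Moment checks use 1e5 trials (sampling error well under the 1% band);
CDF-vs-Monte-Carlo agreement uses 1e6 draws and a 3-binomial-SE criterion;
parameter recovery uses n = 1000; the null (type-I) study uses 400
replicate pairs at 500 trials per condition; the verdict studies use 200
replicates per intervention at 500 trials per condition — sizes at which
every rate estimate has a binomial SE below 1.6 percentage points.
Scale guards: promptness SDs are floored at 1e-10 inside EM; degenerate
zero-variance samples raise rather than fit; bootstrap intervals are
percentile-based and seeded.

## What the generator does and does not emulate

The simulator produces the model's own world: exactly recinormal main
latencies, an exactly linear early line, a clean express band, and
stationary parameters within a condition. Real reaction-time data bring
sequential dependencies, parameter drift, anticipations that are not
zero-mean-promptness, and recording artifacts, none of which are modelled.
Passing tests therefore certify the internal consistency of the
model-plus-toolkit (the fitters recover what the generator encodes, and
threshold vs gain changes are distinguishable at realistic sample sizes),
not the model's fit to any empirical dataset. The verdict studies run the
pure recinormal design (early and express pathways off) because the nested
hypotheses describe a single line; with a 5% unmodelled early admixture
the single-line comparison visibly loses accuracy — the mixture fit exists
for exactly that situation.

## Known limitations

* Censored trials enter only the single-component censored likelihood;
  the EM mixture excludes them (kept simple deliberately).
* The swivel/shift comparison assumes pure recinormal samples; early or
  express admixture biases it toward the "full" verdict.
* Early-mode prevalence is a free mixture weight, not a function of the
  modulator state.
* No hierarchical multi-subject structure and no Bayesian posterior
  inference over unit parameters.
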