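# hclsleep

A Python implementation of the **Homeostatic–Circadian–Light (HCL) model**
of human sleep timing: a minimal, transparent model that predicts when a
person falls asleep and wakes up from their light exposure pattern, and
that can be *personalised* — fitted to an individual's wearable light data
and sleep diary to separate the endogenous (physiological) from the
exogenous (environmental light) drivers of their sleep phenotype.

It is written for sleep and circadian researchers who have longitudinal
field data — minute-resolution lux from a wrist or shoulder sensor plus a
consensus sleep diary — and want model-based phenotyping: personalised
parameters, light-exposure metrics, intervention predictions and cohort
statistics.

## The model

Sleep pressure $H(t)$ relaxes exponentially with time constant $\chi$
towards an upper asymptote $\mu$ during wake and towards 0 during sleep:

$$\chi \frac{dH}{dt} = -H + (1 - S)\,\mu,$$

where $S \in \{0, 1\}$ is the sleep state. Switching is threshold-driven:
wake→sleep when $H = H^+(t) = \bar H_0 + \tfrac{1}{2}\Delta + c_a C(t)$ and
sleep→wake when $H = H^-(t) = \bar H_0 - \tfrac{1}{2}\Delta + c_a C(t)$.
The circadian wake-propensity rhythm $C(t)$ (peak-to-peak amplitude ≈ 2,
maximum in the evening, minimum in the second half of the night) is a
quadratic form $C = c_{20} + \alpha_{21}x + \alpha_{22}y + \beta_{21}x^2 +
\beta_{22}xy + \beta_{23}y^2$ in the state of a light-forced van der Pol
pacemaker:

$$\kappa \dot x = \gamma\!\left(x - \tfrac{4}{3}x^3\right)
  - y\left[\left(\tfrac{24}{f\tau_c}\right)^{\!2} + kB\right],
  \qquad \kappa \dot y = x + B,$$

with $\kappa = 24 \times 3600 / 2\pi$ s, intrinsic period $\tau_c$ and
stiffness $\gamma$. Light of intensity $I$ acts through a saturating pool
of activated photoreceptors $n$,

$$\dot n = \alpha_0 (\tilde I / I_0)^p (1 - n) - \beta n,
  \qquad \hat B \propto G\,\alpha_0 (\tilde I/I_0)^p (1 - n),
  \qquad B = (1 - bx)(1 - by)\,\hat B,$$

where $\tilde I = (1 - S) I$: sleep **gates** light (eyes closed), so sleep
timing feeds back on circadian phase. The compressive exponent $p = 0.6$
and the sensitivity factor $(1-bx)(1-by)$ encode the human dose– and
phase-dependence of the light response. All 14 default parameter values
ship with the package (`ModelParams()`).

On top of the simulator the package provides:

- **Personalised fitting** — `fit_mu_tauc` (alternating bracketed root
  solves; duration is monotone in $\mu$, mid-sleep in $\tau_c$) and
  `fit_mu_ca` (Nelder–Mead over $(\mu, c_a)$), both converging to
  residuals under two minutes with a physiological admissibility check
  $\mu > c_a + \bar H_0 + \tfrac{1}{2}\Delta$.
- **Light metrics** — hours of bright light (> 500 lux), mean lux,
  geometric mean, the half-cumulative-light clock times, and the
  **biological effect of light**: feed one day of light into the
  light-circadian model from a fixed reference state and report, in
  minutes, whether the clock covered more (+) or less (−) than one cycle
  in 24 h.
- **Sensitivity and entrainment analysis** — parameter sweeps and
  bisection of the entrainment boundary.
- **Cohort statistics** — random-intercept ICC, Spearman correlations
  with Benjamini–Hochberg FDR control, and the mid-sleep general linear
  model on $(\tau_c, L_{\mathrm{time}})$.
- **Synthetic participants** — seeded generator of light series (with
  day-level jitter and sensor dropouts) plus diaries with known
  ground-truth parameters, closing the parameter-recovery loop.

## Worked example

```python
from hclsleep import ModelParams, simulate_to_convergence
from hclsleep.calibration import default_profile

sim = simulate_to_convergence(ModelParams(), default_profile())
```

Running `python examples/01_simulate_default.py` prints:

```
entrained            : True (after 6 passes)
mean mid-sleep       : 03:16 hh:mm
mean sleep duration  : 7.42 h
typical night        : 23.56 h -> 6.97 h clock time
```

The default parameters with the default light profile (2000 lux from dawn
06:00 to dusk 18:00, 40 lux in the evening) settle to a mean mid-sleep of
03:16 — the timing phenotype of an average ~65-year-old. Dropping evening
light to 10 lux (`examples/02_evening_light.py`) advances mid-sleep to
02:15: about one hour of delay is attributable to the 40-lux evenings
alone. `examples/03_fit_participant.py` closes the recovery loop — a
synthetic participant generated with $(\mu, \tau_c) = (18.3, 24.12)$ is
refitted from their light and diary to $(18.300, 24.117)$ with a residual
of 0.59 minutes.

The other examples cover the light metrics, the $\tau_c$ sensitivity sweep
and entrainment boundary, cohort statistics and light-intervention
predictions. A thin `hcl` command-line interface wraps the same workflows
(`hcl simulate`, `hcl fit`, `hcl metrics`, `hcl sweep`, `hcl light
intervene`, `hcl synth`, `hcl cohort`); every artifact it writes embeds the
fully resolved parameter set.

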