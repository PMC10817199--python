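"""Personalised parameter recovery on a synthetic participant.

A participant with known homeostatic asymptote mu and intrinsic period
tauc is generated (10 days of jittered light with sensor dropouts plus a
sleep diary); wake-time zeros are imputed and the (mu, tauc) pair is
refitted from the diary averages under the participant's own light.
"""

from hclsleep import (LightProfileSpec, ModelParams, diary_to_targets,
                      fit_mu_tauc, generate_participant, impute_wake_zeros)
from hclsleep.synth import SyntheticParticipantSpec

spec = SyntheticParticipantSpec(
    participant_id="demo",
    true_params=ModelParams().replace(mu=18.3, tauc=24.12),
    light_template=LightProfileSpec(evening_level=10.0),
    diary_noise=(0.0, 0.0),  # noise-free diary isolates the estimator
    n_days=10, seed=7)
part = generate_participant(spec)

light = impute_wake_zeros(part.light, part.wake_mask)
targets = diary_to_targets(part.diary)
fit = fit_mu_tauc(light, targets)

print(f"targets      : duration {targets.mean_duration:.3f} h, "
      f"mid-sleep {targets.mean_mid_sleep % 24:.3f} h clock")
print(f"true (mu, tauc)   : ({spec.true_params.mu:.3f}, "
      f"{spec.true_params.tauc:.3f})")
print(f"fitted (mu, tauc) : ({fit.mu:.3f}, {fit.tauc:.3f})")
print(f"residual          : {fit.residual * 60:.2f} min "
      f"(converged={fit.converged}, {fit.n_evaluations} simulations)")
print()
print("Residuals under two minutes mean the fitted model reproduces the")
print("diary's average sleep duration and timing essentially exactly.")
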