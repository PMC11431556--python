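"""Two-step MR mediation: decompose an exposure->outcome effect.

beta1 (exposure->mediator, IVW) times beta2 (mediator->outcome, IVW) is the
mediated effect; its share of the total exposure->outcome effect is the
mediation proportion.  The triple is simulated with known structure
(theta1=0.4, theta2=0.3, direct=0.1), so the true proportion is
0.12/0.22 = 54.5%.
"""

from mrmediate import SimulationConfig, run_mediation, simulate_triple

exposure, mediator, outcome, truth = simulate_triple(SimulationConfig(seed=42))
res, reason = run_mediation(exposure, mediator, outcome)
assert res is not None, reason

print(f"beta1 (exposure->mediator) = {res.beta1:.3f} +- {res.se1:.3f}  (true {truth.theta_xm})")
print(f"beta2 (mediator->outcome)  = {res.beta2:.3f} +- {res.se2:.3f}  (true {truth.theta_my})")
print(f"total effect               = {res.total:.3f} +- {res.se_total:.3f}  (true {truth.true_total:.2f})")
print(f"mediated = beta1*beta2     = {res.mediated:.4f} "
      f"[{res.mediated_ci_low:.4f}, {res.mediated_ci_high:.4f}], p = {res.mediated_pval:.1e}")
print(f"direct   = total-mediated  = {res.direct:.4f}")
print(f"proportion mediated        = {res.proportion_pct:.1f}% "
      f"[{res.proportion_ci[0]:.1f}%, {res.proportion_ci[1]:.1f}%]  (true {truth.true_proportion_pct:.1f}%)")
print(f"pleiotropy flags: {res.flags or 'none'}")
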