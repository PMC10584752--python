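"""Simulate the four Bayes-rational observers on both tasks.

Each agent watches two noisy channels for 12 time steps (signal evidence
N(0.5, 1), noise N(0, 1)), accumulates log-likelihoods for signal-in-1,
signal-in-2 and signal-absent, reports the maximum-likelihood world state
and rates confidence as the posterior probability of being correct.
"""

import sdtkernels as sk

for model in sk.MODELS:
    cfg = sk.AgentConfig(model=model)
    for task in ("discrimination", "detection"):
        table = sk.simulate_campaign(cfg, task, n_agents=20, n_trials=50, seed=1)
        print(
            f"{model:17s} {task:15s} accuracy={table.correct.mean():.3f} "
            f"mean confidence={table.confidence.mean():.3f}"
        )

print(
    "\nAccuracy ~0.71 for the vanilla discriminator is the analytic value "
    "Phi(6/sqrt(120)) implied by 12 samples of signal 0.5 with total "
    "variance 5 per channel; attention models are less accurate because "
    "they see only one channel per time step."
)
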