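"""A synthetic luminance-flicker experiment with an evidence boost.

Fifty synthetic subjects view two 4-bar patches flickering for 12 frames
at 25 Hz (background 128/255, signal patch 133/255, bar SD 10/255). On
half of the trials both patches are brightened by 2/255 -- raising sum
evidence without touching relative evidence. A Bayes-rational (vanilla)
observer should then respond 'yes' more often and be more confident in
'yes' responses on boosted trials.
"""

import sdtkernels as sk

observer = sk.ObserverSpec(kind="bayes_agent", agent_config=sk.AgentConfig())
design = sk.ExperimentDesign(n_subjects=50, trials_per_task=56, boost_fraction=0.5, seed=7)
table = sk.run_synthetic_experiment(sk.StimulusSpec(), observer, design)

print(f"{len(table)} trials from {design.n_subjects} synthetic subjects")
contrast = sk.boost_contrast(table)
for key in ("p_yes", "yes", "no", "discrimination"):
    s = contrast.group[key]
    label = "delta P(yes)" if key == "p_yes" else f"delta confidence ({key})"
    print(f"  {label:28s} mean={s.mean:+.4f}  t({s.df})={s.t:+.2f}  p={s.p:.3g}")

print(
    "\nThe boost raises the 'yes' rate and 'yes' confidence and lowers "
    "'no' confidence: total brightness is a valid cue for presence, so a "
    "rational detector weighs it positively."
)
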