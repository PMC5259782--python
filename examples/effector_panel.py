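"""Effector relative-activity panel with replicate statistics.

Reconstructs a metabolite panel at a half-saturating substrate: each
effector's velocity is a fraction of the mock mean, with 5% replicate noise.
Reports relative activity (% of mock) +/- SD and a paired t-test, then
compares one effector across two pH values.
"""

from cladekin import inhibition_vs_ph, relative_activity
from cladekin.synth import generate_effector_panel

panel, truth = generate_effector_panel(
    mock_velocity=1.044e-3,  # units at 0.5 mM PEP
    activity_fractions={
        "aspartate": 0.852,
        "malate": 0.771,
        "fumarate": 0.750,
        "succinate": 1.24,
    },
    n_replicates=3,
    noise_cv=0.05,
    seed=3,
)

print("effector       rel. activity (% of mock)   p (paired t)")
for name in ("aspartate", "malate", "fumarate", "succinate"):
    eff = relative_activity(panel[name], panel["MOCK"], name, 1.0)
    p = f"{eff.p_value:.3f}" if eff.p_value is not None else "n/a"
    print(f"{name:<12}  {eff.relative_activity:6.1f} +/- {eff.sd:4.1f}          {p}")
# Values scatter around the generating fractions (85.2, 77.1, 75.0, 124%);
# the t-test asks whether each effector's replicates differ from mock.

low = relative_activity(
    [v * 0.85 for v in panel["MOCK"]], panel["MOCK"], "malate", 1.0, pH=7.3
)
high = relative_activity(
    [v * 0.60 for v in panel["MOCK"]], panel["MOCK"], "malate", 1.0, pH=9.0
)
table = inhibition_vs_ph([low, high])
print(table.to_string(index=False))
# `enhanced_at_higher_ph` is flagged because relative activity drops from
# 85% at pH 7.3 to 60% at pH 9.0: inhibition strengthens in alkaline
# conditions even though catalytic activity itself peaks near pH 7.3.
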