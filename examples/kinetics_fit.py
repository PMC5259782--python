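"""Michaelis-Menten fitting and inhibition-mode classification.

Generates a noiseless PEP titration at the wild-type parameters
(Vmax 1.74 units/mg with 4 pmol = 0.6 ug enzyme, Km 0.34 mM), fits it by the
double-reciprocal (Lineweaver-Burk) stage, then adds an effector that raises
both Vmax and Km - the kinetic signature malate and fumarate show on PEPC -
and classifies the mode.
"""

from cladekin import classify_inhibition_mode, fit_michaelis_menten
from cladekin.kinetics import MOCK, measurements_from_table
from cladekin.synth import AssaySimConfig, EffectorSpec, generate_assay_dataset

vmax_units = 1.74 * 0.6 / 1000.0  # units/mg -> units in the cuvette (0.6 ug)
config = AssaySimConfig(
    variants={"SyPEPC": (vmax_units, 0.34)},
    substrate_mM=[0.125, 0.25, 0.5, 1, 2, 4],
    seed=0,
    noise_cv=0.0,
    n_replicates=1,
    effectors={"malate": EffectorSpec(vmax_factor=1.26, km_factor=2.4)},
)
table, truth = generate_assay_dataset(config)

fits = {}
for effector in (MOCK, "malate"):
    meas = measurements_from_table(table[table.effector == effector])
    fit = fit_michaelis_menten(meas, "LB", protein_pmol=4.0, protein_ug=0.6)
    fits[effector] = fit
    print(
        f"{effector:>6}: Km = {fit.Km:.3f} mM, Vmax = {fit.Vmax_per_mg:.3f} units/mg "
        f"(r^2 = {fit.r_squared:.6f}, {fit.method})"
    )
# The mock fit returns exactly the generating parameters (0.34 mM, 1.74
# units/mg): the double-reciprocal stage is distortion-free on clean data.

mode = classify_inhibition_mode(fits[MOCK], fits["malate"])
print(f"malate mode: {mode}")
# Both Vmax and Km rose beyond the 15% tolerance -> the mixed
# "Km-and-Vmax-increase" signature rather than textbook competitive
# inhibition.

nls = fit_michaelis_menten(
    measurements_from_table(table[table.effector == MOCK]), "NLS"
)
print(f"NLS cross-check: Km = {nls.Km:.3f} mM (agrees with LB on clean data)")
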