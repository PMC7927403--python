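"""Dose-response, competition-binding, kinetic and proliferation analytics.

Round-trips each assay model: a noisy cAMP 3PL curve, a competition
displacement curve converted to pKi with Cheng-Prusoff (KD = 65 nM,
[L] = 300 nM tracer), an association-then-dissociation kinetic trace, and a
proliferation curve condensed into the pIC50 x span factor.
"""

from conformo import pharmacology as pharm
from conformo.synthetic import AssayCurveSpec, make_assay

# 1. cAMP accumulation: 3PL with unit Hill slope
camp, _ = make_assay(AssayCurveSpec(
    params=(("basal", 0.0), ("emax", 100.0), ("pec50", 7.32)), noise_sigma=5.0, seed=1))
fit = pharm.fit_3pl(camp)
print(f"cAMP fit: pEC50 = {fit.pec50:.2f} +/- {fit.se_pec50:.2f}, "
      f"range = {fit.range:.0f} % (generated at 7.32)")

# 2. competition binding -> Ki via Cheng-Prusoff
comp, _ = make_assay(AssayCurveSpec(
    model="competition",
    params=(("pki", 6.39), ("hot_conc", 300e-9), ("hot_kd", 65e-9),
            ("top", 100.0), ("bottom", 0.0)),
    noise_sigma=2.0, n_points=12, seed=2))
kfit = pharm.fit_competition(comp)
print(f"competition fit: pKi = {kfit.pki:.2f} (generated at 6.39), "
      f"full displacement: {kfit.full_displacement}")
print(f"worked Cheng-Prusoff value: IC50 1 uM -> "
      f"Ki = {pharm.cheng_prusoff_ki(1e-6, 300e-9, 65e-9) * 1e9:.1f} nM")

# 3. tracer kinetics: association for 19 min, then displacement
kin_table, _ = make_assay(AssayCurveSpec(
    model="assoc_dissoc",
    params=(("beq", 1.0), ("kobs", 0.3), ("koff", 0.1), ("injection_time", 19.0)),
    noise_sigma=0.01, n_points=60, n_replicates=1, seed=3))
kin = pharm.fit_association_dissociation(
    kin_table["time_min"].to_numpy(), kin_table["signal"].to_numpy(), 19.0, hot_conc=40e-9)
print(f"kinetic fit: kobs = {kin.kobs:.2f}/min, koff = {kin.koff:.2f}/min, "
      f"KD = {kin.kd * 1e9:.1f} nM (generated at 20 nM)")

# 4. proliferation factor: potency x efficacy of growth inhibition
prolif, _ = make_assay(AssayCurveSpec(
    params=(("basal", 100.0), ("emax", 40.0), ("pec50", 5.8)), noise_sigma=5.0, seed=4))
pfit = pharm.fit_3pl(prolif, basal_fixed=100.0)
res = pharm.proliferation_factor(pfit.pec50, 100.0 - pfit.emax)
print(f"proliferation: pIC50 = {pfit.pec50:.2f}, span = {100 - pfit.emax:.0f} % "
      f"-> factor = {res.proliferation_factor:.0f}")
print("\nThe factor rewards compounds that are both potent (high pIC50) and")
print("efficacious (large span of growth inhibition).")
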