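"""Fit the phase models to a simulated pigeon-style experiment.

Generates the full seven-phase design at the study's peck counts, extracts
per-peck kinematics, then fits the binomial success GLMM and the Gaussian
grasping-onset LMM (both with a per-individual random intercept) and prints
the statistics a phase comparison rests on.
"""

from peckkit import extract_batch, pigeon_like_config, records_to_frame, simulate_experiment
from peckkit.pipeline import refit_from_kinematics

trials, _ = simulate_experiment(pigeon_like_config(seed=11))
kin = records_to_frame(extract_batch(trials))
res = refit_from_kinematics(kin)

print(f"{len(kin)} pecks extracted, {int(kin['retained'].sum())} retained")
print()
succ = res["success_lrt"].iloc[0]
print(f"success ~ phase + (1|individual):  chi2({succ['df']:.0f}) = "
      f"{succ['chisq']:.2f}, p = {succ['p']:.2g}")
print(f"  dispersion ratio = {res['success_dispersion']:.2f}  (~1 means the "
      "binomial variance assumption holds)")
onset = res["onset_lrt"].set_index("term")
print("onset ~ phase + distance + acceleration + (1|individual):")
for term in ("phase", "distance_cm", "accel_cm_s2"):
    row = onset.loc[term]
    print(f"  {term:12s} chi2({row['df']:.0f}) = {row['chisq']:8.2f}, "
          f"p = {row['p']:.2g}")
r2m, r2c = res["onset_r2"]
print(f"  marginal R2 = {r2m:.3f}, conditional R2 = {r2c:.3f}")
print()
print("phase 95% CIs for adjusted grasping onset (s), vs control:")
for ci in res["onset_cis"]:
    mark = " *" if ci.differs_from_control else ""
    print(f"  {ci.phase:9s} {ci.estimate:6.3f} [{ci.lower95:6.3f}, "
          f"{ci.upper95:6.3f}]{mark}")
print()
print("A negative removal-phase shift flagged (*) below the control interval")
print("is the motor after-effect: the bird keeps opening its bill early")
print("after the artificial extension is removed.")
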