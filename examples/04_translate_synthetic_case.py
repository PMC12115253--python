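"""The full monkey-to-human translation workflow on a synthetic case study.

Generates a virtual mAb with known ground truth (noisy observed PK in monkey
and human), predicts the monkey with minimal inputs, then runs the three
human scenarios: no additional clearance, allometrically scaled from the
monkey fit, and optimised against the human data.  Takes ~1.5 minutes.
"""

from igpbpk import load_physiology
from igpbpk.calibrate import run_translation_workflow, setup_context
from igpbpk.synthetic import SyntheticCaseConfig, make_case

ctx = setup_context(load_physiology("monkey"), load_physiology("human"))

cfg = SyntheticCaseConfig(seed=11, case_id="demo", monkey_data=True,
                          monkey_cladd_mode="allometric_consistent",
                          cladd_fraction_range=(0.55, 0.55), noise_cv=0.15,
                          dose_levels_mg_per_kg=(3.0, 10.0))
case = make_case(cfg, ctx)
wr = run_translation_workflow(case, ctx)

print(wr.summary_frame().to_string(index=False,
                                   float_format=lambda v: f"{v:+.1f}"))
print(f"\nfitted clearances (L/h): monkey {wr.cl_add_monkey_fit:.5f}, "
      f"human optimized {wr.cl_add_by_scenario['optimized']:.5f}, "
      f"allometric {wr.cl_add_by_scenario['allometric']:.5f}")
print(f"true human cl_add       : "
      f"{case.ground_truth['cl_add_human']:.5f} L/h")
# Expected pattern: without additional clearance the human AUC is
# overpredicted far beyond the +50% margin; the allometrically scaled and
# optimised clearances bring the prediction error inside +/-50%.
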