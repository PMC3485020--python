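"""The shank axial-rotation experiment on one synthetic jump.

Runs the five rotation conditions (and the doubled-bound condition), then
prints the percentage change of the knee-rotator muscle impulses and the
peak anterior-posterior shear relative to the unrotated trial, phase by
phase. Internal rotation is positive; anterior shear is negative.
"""

import pandas as pd

import limbloads as ll
from limbloads.io import RunConfig

pd.set_option("display.width", 120)
pd.set_option("display.float_format", lambda v: f"{v:8.1f}")

trial = ll.generate_jump(ll.JumpParams())
results = ll.run_battery(trial.markers, trial.ground_reaction,
                         trial.params.subject, RunConfig(), model=trial.model)
for r in results:
    print(f"{r.condition.label:12s} unsolved {r.unsolved_pct:5.2f}%")

tables = ll.compare_to_original(results)
for label in ("rot-0.10", "rot+0.10", "double_bound"):
    print(f"\npercent change vs original - {label}")
    print(tables[label].loc[["shear_ap", "pfj", "popliteus", "tfl",
                             "plantaris", "sartorius"]])
print("\n-> popliteus force falls with external (negative) rotation and")
print("   rises with internal rotation; the anterior shear peak moves the")
print("   same way; doubling the rotator bounds reshapes recruitment.")
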