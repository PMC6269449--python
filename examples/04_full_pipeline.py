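"""Run the full analysis on a synthetic 23-site trial network.

Stages: quartile grouping of sites by control RAU_R6, one beta curve per
(group, treatment) cell, AICc comparison of control vs each fertilized
treatment, phenology de-trending with residual regressions, and per-site
summaries.  The report is deterministic for a fixed seed.
"""

import pandas as pd

from bnfcurve import PipelineConfig, SimulationSpec, run_full_pipeline

report = run_full_pipeline(PipelineConfig(simulation=SimulationSpec(), seed=1))

print("group sizes:", report["groups"]["sizes"])
fits = pd.DataFrame(report["curve_fits"])
print(fits[["group", "treatment", "rau_max", "t_half", "max_rate", "r2"]]
      .round(3).to_string(index=False))
cmp = pd.DataFrame(report["aicc_comparisons"])
print(cmp[["group", "treatment", "delta", "preferred"]].round(1).to_string(index=False))
# "separate" means AICc judges that treatment's seasonal curve genuinely
# different from the unfertilized control within that fixation group;
# late N (N_R2) depresses the peak most and is separated most often.
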