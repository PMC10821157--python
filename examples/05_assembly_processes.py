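"""Null-model partition of community assembly processes.

Runs betaNTI and RCbray on a survey simulated under homogeneous
selection and reports the five-process partition plus the
betaNTI-vs-environment correlation.
"""

import numpy as np

from lakemicro import (SimulationConfig, beta_nti, bnti_env_correlation,
                       classify_processes, raup_crick_bray,
                       simulate_metacommunity)
from lakemicro.simulate import REGIME_STUDY_OVERRIDES

cfg = SimulationConfig(n_groups=4, samples_per_group=3,
                       regime="homogeneous_selection", seed=1,
                       **REGIME_STUDY_OVERRIDES["homogeneous_selection"])
cm, tree, env, truth = simulate_metacommunity(cfg)

bnti = beta_nti(cm, tree, n_null=199, seed=0)
rc = raup_crick_bray(cm, n_null=199, seed=0)
iu = np.triu_indices(cm.n_samples, 1)
print(f"median betaNTI = {np.nanmedian(bnti.to_numpy()[iu]):.2f} "
      "(< -2 means communities are more phylogenetically similar than chance)")

res = classify_processes(bnti, rc)
print("\nprocess fractions (% of sample pairs):")
print(res.fractions.round(1).to_string())
print(f"\ngenerating regime was: {truth['regime']}")

corr = bnti_env_correlation(bnti, env, variables=["pH", "DOC", "SAL"],
                            n_perm=199, seed=0)
print("\nSpearman betaNTI vs |delta environment|:")
print(corr.round(3).to_string(index=False))
# The modal process should match the generating regime; the Delta-env
# correlations show which measured gradients track the shift between
# deterministic and stochastic turnover.
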