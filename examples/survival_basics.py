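"""Kaplan-Meier, Nelson-Aalen, logrank and maximally selected cut-offs on a
small synthetic cohort's overall-survival records."""

import numpy as np

from radsurv import (CohortSpec, generate_cohort, kaplan_meier, logrank_test,
                     nelson_aalen, optimal_cutoff)

cases, records = generate_cohort(CohortSpec(n_cases=80, seed=3))
time = np.array([r.time for r in records["OS"]])
event = np.array([r.event for r in records["OS"]])

km = kaplan_meier(time, event)
na = nelson_aalen(time, event)
print(f"S(12 mo) = {km.evaluate([12.0])[0]:.3f}  "
      f"(survival probability at one year)")
print(f"H(12 mo) = {na.evaluate([12.0])[0]:.3f}  "
      f"(cumulative hazard at one year)")

# dichotomize by the hidden latent risk: the logrank cut-off search should
# find a threshold that separates survival strongly
risk = np.array([c.latent_risk for c in cases])
cut = optimal_cutoff(risk, time, event)
print(f"best cut-off on latent risk: {cut.threshold:.2f} "
      f"(chi2 = {cut.logrank_statistic:.1f}, p = {cut.p_value:.2g}, "
      f"groups {cut.n_low}/{cut.n_high})")

low = risk <= cut.threshold
stat, p = logrank_test(time[low], event[low], time[~low], event[~low])
print(f"logrank at that threshold: chi2 = {stat:.1f}, p = {p:.2g}")
# The p-value of a maximally selected statistic is optimistic: the scan
# maximizes over thresholds and applies no multiplicity correction.
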