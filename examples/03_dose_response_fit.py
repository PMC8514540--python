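"""Fit a 4PL dose-response curve and report pIC50 with 95% CI.

Simulates normalized viability responses for a sixfold dilution series
(four replicates, 5% noise) from a known curve, fits the
four-parameter logistic with the top pinned at 100%, and compares two
fitted conditions with a z-test.
"""

import numpy as np

import hcscreen as h

rng = np.random.default_rng(42)
cond = h.TreatmentCondition(components=(("lomustine", 1.0),),
                            top_concentration=100.0, n_points=8)
conc = np.repeat(h.make_dilution_series(cond)["lomustine"], 4)

true_pic50 = 5.0  # IC50 = 10 uM
responses = h.four_param_logistic(conc, 0.0, 100.0, true_pic50, 1.5)
responses = responses + rng.normal(0, 5.0, conc.size)

fit = h.fit_4pl(h.DoseResponseCurve(conc, responses, condition=cond.name))
lo, hi = fit.pic50_ci95
print(f"pIC50 = {fit.pic50:.2f} [{hi:.2f} to {lo:.2f}]   "
      f"IC50 = {h.pIC50_to_IC50(fit.pic50):.1f} uM")
print(f"bottom plateau = {fit.bottom:.1f}%   hill = {fit.hill:.2f}")

# a five-fold more potent condition, compared by z-test
potent = h.four_param_logistic(conc, 0.0, 100.0, true_pic50 + np.log10(5), 1.5)
fit2 = h.fit_4pl(h.DoseResponseCurve(conc, potent + rng.normal(0, 5.0, conc.size)))
diff, z, p = h.compare_pIC50(fit2, fit)
print(f"delta pIC50 = {diff:.2f}, z = {z:.1f}, P = {p:.2g}")
# P < 0.05 flags the second condition as significantly more potent.
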