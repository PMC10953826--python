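"""Fit a 4PL concentration-response curve to a simulated potent compound.

Simulates quadruplicate % live clusters readouts for a compound with a true
IC50 of 16 nM on an 8-point 3.16-fold dilution series (10 uM down to
~3.2 nM, bracketing the IC50), then fits the four-parameter logistic model.
The printed IC50 should land within a few percent of 0.016 uM; top/bottom
are the fitted response plateaus and the negative hill sign records that
the response rises with dose (reversal readout).
"""

from admscreen import fit_4pl, make_dilution_series
from admscreen.doseresp import simulate_dose_response

TRUE_IC50 = 0.016  # uM (16 nM)
doses = make_dilution_series(top_dose=10.0, n_points=8, factor=3.162)
data = simulate_dose_response(TRUE_IC50, doses, top=90.0, bottom=5.0,
                              hill=-1.5, noise_sd=3.0, replicates=4,
                              rng_seed=1)
fit = fit_4pl(data["dose"], data["response"])

print(f"doses (uM): {[round(d, 4) for d in doses]}")
print(f"fitted IC50 = {fit.ic50 * 1000:.1f} nM (true 16 nM), "
      f"hill = {fit.hill:.2f}")
print(f"plateaus: bottom = {fit.bottom:.1f}%, top = {fit.top:.1f}% "
      f"live clusters; rss = {fit.rss:.1f}; converged = {fit.converged}")
print(f"relative IC50 error: {abs(fit.ic50 - TRUE_IC50) / TRUE_IC50:.1%}")
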