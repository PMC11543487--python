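"""Recover enzyme and coenzyme half-lives from first-order decay series.

Generates a noiseless 14-day residual-activity series for the 20% DES-in-
buffer dilution (half-life 29.9 days) and a noisy replicate, then refits
both. The printed half-lives are in days; the noisy fit illustrates the
assay-level scatter the fitter tolerates.
"""

import numpy as np

from descreen.kinetics import fit_first_order_decay, rate_from_half_life
from descreen.synthetic_data import gen_decay

schedule = np.arange(0.0, 15.0)  # daily sampling, day 0..14
k_true = rate_from_half_life(29.9)

clean = gen_decay(k_true, 100.0, schedule, noise_sd=0.0, seed=1)
noisy = gen_decay(k_true, 100.0, schedule, noise_sd=0.05, seed=1)

for label, series in (("noiseless", clean), ("5% assay noise", noisy)):
    fit = fit_first_order_decay(series)
    print(f"{label:>14}: k = {fit.rate_constant:.5f} /day, "
          f"half-life = {fit.half_life:.2f} days (R^2 = {fit.goodness:.4f})")

# The noiseless fit returns the generating half-life exactly; the noisy one
# lands within a few percent, matching triplicate-assay reproducibility.
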