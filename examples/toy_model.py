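"""Toy steady-state model: translation amplifies transcriptional signals.

Generates 5,854 genes with lognormal mRNA levels and a translation rate
that rises as the 0.56 power of (noisy) mRNA level, then reports the
statistics a genome-scale analysis would measure: a high log-log
mRNA-protein correlation (~0.92) together with a log-log slope well above
one (~1.69), showing that a near-perfect correlation coexists with strong
post-transcriptional amplification.
"""

import numpy as np

import noisecorr as nc

report = nc.run_full_pipeline({"seed": 115})
print(f"genes simulated                    : {report['n_genes']}")
print(f"Pearson(ln M, ln P)                : {report['correlation_mrna_protein']:.3f}")
print(f"OLS log-log slope (noise-blind)    : {report['ols_slope']:.3f}")
print(f"RMA log-log slope (noise-aware)    : {report['rma_slope']:.3f}")
print(f"RMA slope, translation rate vs mRNA: {report['rma_slope_translation_rate']:.3f}")
print(f"dynamic range ratio (central 95%)  : {report['dynamic_range']['central']:.2f}")
print(f"mRNA molecules/cell (rescaled sum) : {report['mrna_molecules_per_cell_total']:.0f}")
print()
print("The RMA slope ~1.69 is the amplification exponent A in P ~ M^A;")
print("the OLS slope is biased toward 1 by regression dilution.")

# closed-form check by variance propagation
from noisecorr.simulate import (
    toy_model_expected_correlation, toy_model_expected_slope)
p = nc.ToyModelParams()
print(f"analytic correlation/slope         : "
      f"{toy_model_expected_correlation(p):.3f} / {toy_model_expected_slope(p):.3f}")
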