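"""Trait preparation: log transforms, size correction, imputation, PCA.

Runs a raw morphology + environment table through the standard preparation
chain and prints what each step does to the numbers.
"""

import numpy as np
import pandas as pd

import pcmkit as pk
from pcmkit.traits import TraitMatrix

# raw specimen-style morphology (mm): snout-vent length + two limb measures
morph = TraitMatrix(pd.DataFrame({
    "SVL": [50.0, 55.0, 60.0, 48.0],
    "AG":  [10.0, 11.5, 12.0, np.nan],   # one missing axilla-groin length
    "TbL": [8.0, 8.6, 9.5, 7.8],
}, index=["sp1", "sp2", "sp3", "sp4"]))

filled = pk.impute_by_regression(morph, "AG", "SVL")
print("imputed AG for sp4:", round(filled.data.loc["sp4", "AG"], 3),
      "(from the AG ~ SVL regression)")

shape = pk.size_correct(filled)
print("\nlog-ratio shape table (ln x - ln SVL; SVL kept as ln body size):")
print(shape.data.round(3))

# environment variables on heterogeneous scales, with the conventional
# pre-adjustments before the natural log
env = TraitMatrix(pd.DataFrame({
    "seasonality": [400.0, 650.0, 900.0, 500.0],   # percent-scaled
    "min_temp": [-5.0, 0.0, 4.0, -2.0],            # can be negative
    "dry_prec": [0.0, 3.0, 10.0, 1.0],             # can be zero
}, index=["sp1", "sp2", "sp3", "sp4"]))
logged = pk.env_log_transform(env, {
    "seasonality": "divide100_log",
    "min_temp": ("offset_log", 100),
    "dry_prec": ("offset_log", 1),
})
print("\nlog-transformed environment:")
print(logged.data.round(3))

pca = pk.pca_reduce(logged, var_threshold=0.99)
print("\nPCA on the correlation matrix: axis variance fractions",
      np.round(pca.variance_fraction, 3), "->", pca.n_retained, "axes retained")
print(pca.scores.round(3))
# The retained axes are what downstream regressions use as environmental
# predictors; loadings (pca.loadings) say which variables drive each axis.
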