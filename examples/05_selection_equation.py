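"""Stepwise selection equation: which trait classes predict a high F-value.

Because F is built from the trait indicators, a stepwise OLS of F on those
indicators compresses the composite evaluation into a short field-usable
equation: score an accession by adding the coefficients of the classes it
carries.  Positive coefficients mark favorable classes.
"""

import warnings

import numpy as np
import germeval as g

warnings.filterwarnings("ignore")  # one-hot twins trigger collinearity notes

scheme = g.default_scheme()
table = g.sample_accessions(g.SyntheticConfig(n_accessions=288, seed=1))

matrix = g.encode_indicators(table, scheme)
model = g.fit_pca(matrix)
scores = g.component_scores(model, matrix)
comps = [0, 1, 2]
f = g.f_value(g.membership_rescale(scores, comps), model, comps)

sw = g.fit_stepwise(matrix, f["F"].to_numpy(),
                    entry_alpha=0.05, removal_alpha=0.10)
print(sw.equation())
print(f"\n{len(sw.terms)} terms admitted; R = {sw.r:.3f}, R^2 = {sw.r2:.3f}")

yhat = g.predict(sw, matrix)
err = np.abs(yhat - f["F"].to_numpy()).max()
print(f"max |predicted - actual F| on the collection: {err:.4f}")
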