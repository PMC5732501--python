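"""Generate the three synthetic areal data regimes and test for autocorrelation.

Each regime places a different underlying spatial random field (USRF) on a
12×12 grid: pure noise, a smooth autocorrelated surface, and four clusters of
elevated values.  Observed counts are Poisson draws around expected counts
modulated by the field and a correlated covariate.  Moran's I on the observed
counts (binary first-order weights, permutation test) shows which regimes
carry detectable spatial structure.
"""

import numpy as np

import bymweights as bw

a1 = bw.build_weights("A1", bw.grid_lattice(12, 12))
print(f"{'regime':<10}{'total y':>9}{'Moran I':>9}{'perm p':>10}   interpretation")
for regime in ("noise", "smooth", "clusters"):
    data, comps, geom = bw.generate_dataset(regime, bw.GeneratorConfig(seed=1))
    i_obs = bw.morans_i(data.y.astype(float), a1)
    p = bw.morans_p(data.y.astype(float), a1, n_perm=9_999, seed=1)
    verdict = "spatially autocorrelated" if p < 0.05 else "no detectable structure"
    print(f"{regime:<10}{data.y.sum():>9}{i_obs:>9.3f}{p:>10.4f}   {verdict}")

print("\nA small p-value rejects spatial randomness of the observed counts;")
print("the smooth and clusters regimes are built to be strongly autocorrelated,")
print("the noise regime is not.")
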