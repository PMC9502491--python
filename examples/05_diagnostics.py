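"""Goodness-of-fit diagnostics of a fitted (here: known) population model.

Simulates a study under the model and computes IWRES, NPDE and VPC bands;
under a correct model IWRES/NPDE are ~N(0,1) and observed percentiles stay
inside their simulated prediction bands.
"""

import numpy as np
from scipy import stats

from nebpk import default_population_model, generate_dataset, npde, vpc
from nebpk.estimation import fit_from_population_model
from nebpk.diagnostics import gof_table

pm = default_population_model()
ds = generate_dataset(seed=5)

fit = fit_from_population_model(ds, pm)  # evaluation at the known values
gof = gof_table(ds, pm, fit=fit, k_npde=300, seed=6)
iw = gof["IWRES"].to_numpy()
iw = iw[np.isfinite(iw)]
print(f"IWRES: mean {iw.mean():+.3f}, variance {iw.var():.3f} "
      "(target: 0 and ~1; EBE shrinkage deflates the variance slightly)")

e = npde(ds, pm, k=300, seed=9)
e = e[np.isfinite(e)]  # pre-lag zeros carry no distributional information
sh = stats.shapiro(e)
print(f"NPDE : mean {e.mean():+.3f}, variance {e.var():.3f}, "
      f"Shapiro p={sh.pvalue:.2f} (non-rejection = no misfit signal)")

v = vpc(ds, pm, n_sim=300, bins=6, seed=8)
n_out = int(v.outliers.sum())
print(f"VPC  : {n_out}/{v.outliers.size} observed percentile points outside "
      f"their {v.level:.0f}% prediction band")
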