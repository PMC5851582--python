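"""Calibrate a boosted-tree model for coral cover and inspect it.

Surveys are synthetic (known driver-response functions + 25 % noise); the
model is fit on the square-root-transformed cover with a small hyperparameter
grid and ten-fold cross-validated tree selection.
"""

import numpy as np

from ridge2reef import generate_site, generate_surveys
from ridge2reef.brt import BRTConfig, fit_brt, partial_dependence, sample_at_points, transform_response
from ridge2reef.pipeline import run_land_sea

site = generate_site("wet", size=40, seed=1)
stack = run_land_sea(site).driver_stack
surveys, truth = generate_surveys(stack, n=300, seed=2)

X = sample_at_points(stack, surveys["x"].to_numpy(), surveys["y"].to_numpy())
y = transform_response(surveys["coral"].to_numpy(), "sqrt")
model = fit_brt(X, y, response="coral", transform="sqrt",
                config=BRTConfig(grid=((0.05, 3, 0.75),), max_trees=250),
                response_upper=100.0)

print(f"winner: lr={model.lr}, tc={model.tc}, bag={model.bag}, trees={model.n_trees}")
print(f"PDE = {100 * model.pde:.1f} %, CV PDE = {100 * model.cv_pde:.1f} %")
print("\nrelative influence (%):  [truth drivers:", truth.indicators["coral"]["drivers"], "]")
for d, v in sorted(model.relative_influence.items(), key=lambda kv: -kv[1])[:6]:
    print(f"  {d:12s} {v:5.1f}")
grid = np.linspace(np.nanmin(stack["freshwater"].values),
                   np.nanmax(stack["freshwater"].values), 5)
curve = partial_dependence(model, "freshwater", grid, X)
print("\nfreshwater response curve (transformed scale):")
for g, c in zip(grid, curve):
    print(f"  {g:12,.0f} -> {c:.2f}")

# Influence concentrates on the truth drivers (or their >0.7-correlated
# aliases), and the freshwater curve declines: coral avoids low salinity.
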