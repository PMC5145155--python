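"""The Ih current: equilibrium-branch folds, the cusp, and hysteresis ramps.

Traces the reduced-model equilibrium branch versus applied current for a
range of Ih conductances, bisects the critical g_h at which the branch
folds vanish, and runs rising/falling current ramps probing bistability.
Writes results/ih_branches.csv and results/ih.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dopadyn import ModelVariant, default_params
from dopadyn.dynamics_analysis import (bistability_window, branch_has_fold,
                                       equilibrium_branch,
                                       ih_fold_critical_gh)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = default_params()
red_ih = ModelVariant.reduced(include_ih=True)
v_grid = np.linspace(-90.0, -25.0, 600)

frames = []
for gh in (0.0, 3.5, 7.0, 9.0):
    p = params.replace(g_h=gh)
    i_app = equilibrium_branch(p, red_ih, v_grid=v_grid)
    frames.append(pd.DataFrame({"g_h": gh, "v_mV": v_grid,
                                "i_app": i_app,
                                "has_fold": branch_has_fold(p, red_ih)}))
    print(f"g_h={gh}: equilibrium branch folded = {branch_has_fold(p, red_ih)}")
pd.concat(frames).to_csv(OUT / "ih_branches.csv", index=False)

gh_c = ih_fold_critical_gh(params)
print(f"critical g_h (folds vanish): {gh_c:.2f} mS/cm^2")

windows = {}
for gh, irange in ((0.0, (-12.0, 0.5)), (3.5, (-25.0, 0.5)),
                   (7.0, (-45.0, 0.5))):
    p = params.replace(g_h=gh)
    var = ModelVariant.reduced(include_ih=gh > 0)
    w = bistability_window(p, var, i_range=irange, n_points=60,
                           duration=8000.0)
    windows[gh] = w
    print(f"g_h={gh}: hysteresis window {w:.3f} uA/cm^2")

(OUT / "ih.json").write_text(json.dumps(
    {"gh_critical": gh_c, "hysteresis_windows": windows}, indent=2,
    default=float))
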