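"""Tonic NMDA-GABA balance: rate map, balanced band, and reference cell.

Sweeps the tonic conductance plane with the full model, fits the
least-squares line through the low-frequency balanced band (anchored at the
reference cell g_NMDA = 16.9, g_GABA = 5 mS/cm^2), and confirms the
GABA-rescue of depolarization block.  Writes results/balance_heatmap.csv
and results/balance.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dopadyn import ModelVariant, default_params
from dopadyn.simulation_engine import (balance_line, conductance_plane_sweep,
                                       firing_stats, integrate)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = default_params()
full = ModelVariant.full()

res = integrate(params, full, 12000.0, g_nmda=16.9, g_gaba=5.0,
                transient=2000.0)
ref_rate, _ = firing_stats(res.post_transient_spikes, min_isis=2)
print(f"reference cell (16.9, 5): {ref_rate:.2f} Hz")

hmap = conductance_plane_sweep(
    params, full,
    x=("g_nmda", np.linspace(0.0, 40.0, 20)),
    y=("g_gaba", np.linspace(0.0, 6.0, 20)),
    duration=10000.0, transient=2000.0)
slope, intercept, resid = balance_line(hmap, (0.5 * ref_rate, 1.5 * ref_rate))
print(f"balanced band: g_NMDA = {slope:.2f} * g_GABA + {intercept:.2f}")

yy, xx = np.meshgrid(hmap.y_grid, hmap.x_grid, indexing="ij")
pd.DataFrame({"g_nmda": xx.ravel(), "g_gaba": yy.ravel(),
              "rate_hz": hmap.rate.ravel(), "cv": hmap.cv.ravel(),
              "block": hmap.block.ravel()}).to_csv(
    OUT / "balance_heatmap.csv", index=False)

# GABA rescue: high NMDA alone blocks, adding GABA restores firing
blocked = integrate(params, full, 10000.0, g_nmda=16.9, transient=2000.0)
rescued = integrate(params, full, 10000.0, g_nmda=16.9, g_gaba=5.0,
                    transient=2000.0)
rescue = (blocked.post_transient_spikes.size == 0
          and rescued.post_transient_spikes.size > 0)
print(f"GABA rescue of NMDA-induced block: {rescue}")

(OUT / "balance.json").write_text(json.dumps({
    "reference_rate_hz": ref_rate, "slope": slope, "intercept": intercept,
    "fit_residual": resid, "gaba_rescue": bool(rescue)}, indent=2))
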