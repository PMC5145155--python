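"""Excitability typing: which currents and synapses set type I vs type II.

Classifies the spiking-to-rest transition for (i) the reduced model under
growing GABA (type I via SNIC-like slow passage), (ii) the pure Ca-K
oscillator without subthreshold Na, (iii) the full spiking model (same
verdict as reduced), and (iv) the combined ohmic synapse at hyperpolarized
versus depolarized reversal potentials, including the type I/II boundary.
Writes results/excitability.json.
"""

import json
from pathlib import Path

import numpy as np

from dopadyn import ModelVariant, default_params
from dopadyn.dynamics_analysis import bt_boundary, classify_transition

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = default_params()
out = {}

# refine tolerances chosen so 60 s onset runs resolve rates below the
# 0.5 Hz type threshold right up to the critical parameter
cases = [
    ("reduced_gaba", ModelVariant.reduced(), "g_gaba", [0.0, 3.0], {}, 1e-3),
    ("ca_k_only_gaba", ModelVariant.ca_k_only(), "g_gaba", [0.0, 3.0], {},
     1e-3),
    ("full_gaba", ModelVariant.full(), "g_gaba", [0.0, 3.0], {}, 1e-3),
    ("ohmic_minus90", ModelVariant.reduced(), "g_eff", [0.0, 20.0],
     {"e_eff": -90.0}, 4e-3),
    ("ohmic_minus60", ModelVariant.reduced(), "g_eff", [0.0, 20.0],
     {"e_eff": -60.0}, 4e-3),
]
for name, variant, param, grid, extra, tol in cases:
    bp = classify_transition(params, variant, param, np.array(grid),
                             extra_drive=extra or None, duration=15000.0,
                             onset_duration=60000.0, refine_tol=tol)
    verdict = "I" if bp.onset_rate_hz < 0.5 else "II"
    out[name] = {"kind": bp.kind, "critical_value": bp.value,
                 "onset_rate_hz": bp.onset_rate_hz, "type": verdict}
    print(f"{name}: {bp.kind}, onset {bp.onset_rate_hz:.3f} Hz -> type {verdict}")

bt = bt_boundary(params)
out["type_boundary_e_eff_mV"] = bt
print(f"type I/II boundary at E_eff = {bt:.2f} mV")

(OUT / "excitability.json").write_text(json.dumps(out, indent=2, default=float))
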