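"""Rank all eleven antibody:tumor pairs by tumor uptake.

Same 10 mg dose everywhere, so differences reflect organ physiology
(lymph flow, vascular leakiness, volumes) and target biology alone.
"""

import numpy as np

import tdlnpk as tk

times = np.linspace(0.0, 336.0, 169)
rows = []
for sid in tk.study_ids():
    traj = tk.simulate(tk.get_study(sid), tk.DoseSpec(10.0), times)
    g = tk.summarize_gradient(traj)
    rows.append((sid, g.suv_peak["PT"], g.suv_peak["PT/TDLN"], g.gradient_ratio))

rows.sort(key=lambda r: -r[1])
print(f"{'study':30s} {'peak PT SUV':>12s} {'peak TDLN SUV':>14s} {'PT:TDLN AUC':>12s}")
for sid, pt, ln, ratio in rows:
    print(f"{sid:30s} {pt:12.2f} {ln:14.2f} {ratio:12.2f}")
print("\nThe renal tumor leads the brain (GBM) and lung (NSCLC) studies by "
      "about 3x: the kidney's high perfusion (and hence lymph flow) "
      "delivers more antibody per unit tumor volume.  Very small tumors "
      "(ovarian) also concentrate antibody strongly per litre of "
      "interstitium.  The renal study shows the steepest PT:TDLN "
      "gradient, driven by its high tumor-to-node target ratio "
      "(R01 = 10 vs R02 = 2.5 nM).")
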