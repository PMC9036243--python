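"""Tumor-growth-induced inflammation remodels the drainage network.

Rapid tumor expansion compresses intratumoral lymphatics (afferent flow
~0) while inflammation boosts peritumoral drainage.  The PT efflux then
splits very unevenly between the two node populations.
"""

import numpy as np

import tdlnpk as tk

renal = tk.get_study("bevacizumab_renal")
net = tk.apply_inflammation(renal, [
    tk.TDLNBranch("intratumoral_pos", "intratumoral", "positive"),
    tk.TDLNBranch("intratumoral_neg", "intratumoral", "negative"),
    tk.TDLNBranch("peritumoral_pos", "peritumoral", "positive"),
    tk.TDLNBranch("peritumoral_neg", "peritumoral", "negative"),
])
times = np.linspace(0.0, 336.0, 169)
traj = tk.simulate(net, tk.DoseSpec(10.0), times)

print("TDLN branch          | total-antibody AUC (nM.h) | peak SUV")
for node in net.lesions[0].tdlns:
    label = f"PT/{node.label}"
    auc = float(np.trapezoid(traj.conc[label], times))
    print(f"{node.label:20s} | {auc:25.1f} | {traj.suv[label].max():8.2f}")
print("\nCompressed intratumoral branches (0.01x afferent flow) are "
      "starved regardless of their metastatic status; peritumoral nodes "
      "(2x flow) are overexposed — a mechanism for heterogeneous nodal "
      "responses in the same patient.")
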