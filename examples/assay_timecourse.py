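"""Simulate the coupled synthesis/polymerization fluorometer assay.

The enzyme polymerizes as its product accumulates; adding fresh
substrate at 600 s transiently disassembles the filaments (substrate
competes product off the free tetramer, pulling the assembly
equilibrium back), the synthesis rate spikes, and the polymer reforms
as product accumulates again.
"""

import numpy as np

from ctpspoly import Conditions, Event, EventScript, default_params, simulate_assay

params = default_params()
tc = simulate_assay(
    params,
    Conditions(U=1000.0, C=0.0, E_tot=5.0),
    tau_poly=2.0,
    horizon=1200.0,
    events=EventScript((Event(600.0, "add_UTP", 1000.0),)),
    dt_out=1.0,
)

for t in (0, 300, 599, 603, 610, 700, 1200):
    i = np.searchsorted(tc.t, t)
    i = min(i, len(tc.t) - 1)
    print(f"t = {tc.t[i]:6.0f} s  U = {tc.U[i]:7.1f}  C = {tc.C[i]:7.1f}  "
          f"M = {tc.M[i]:5.2f} uM  v = {tc.v[i]:5.3f} uM/s  "
          f"scatter = {tc.scatter[i]:7.1f} au")

i_ev = np.searchsorted(tc.t, 600.0)
dip = tc.M[i_ev:i_ev + 11].min()
print()
print(f"polymer before addition: {tc.M[i_ev-1]:.2f} uM; dip within 10 s: "
      f"{dip:.2f} uM; final: {tc.M[-1]:.2f} uM")
print("Substrate addition transiently mobilizes the stored enzyme pool —")
print("disassembly, an activity burst, then re-assembly as CTP rebuilds.")
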