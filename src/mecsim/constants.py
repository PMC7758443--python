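"""Physical constants and shared unit conventions.

Units used throughout the package:

* time            ms
* voltage         mV
* concentration   mM
* current density pA/pF
* conductance     nS (junctions) or nS/pF (membrane densities)
* capacitance     pF
* volume          pL
* length          um
* strain rate     1/ms
"""

FARADAY = 96485.0  # C/mol
R_GAS = 8.314  # J/(mol K)
TEMPERATURE = 310.0  # K
RTF = R_GAS * TEMPERATURE / FARADAY * 1000.0  # ~26.71 mV

# With currents in pA and volumes in pL, dC [mM/ms] = I / (z * FARADAY * V):
# 1 pA * 1 ms = 1e-15 C -> /(z * 96485 C/mol) mol -> /(V * 1e-12 L) gives
# 1e-3/(z * 96485 * V) mol/L = 1/(z * 96485 * V) mM.
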