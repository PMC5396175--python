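# Default parameters of the reduced single-compartment Purkinje-cell model.
# Units: conductances mS/cm^2, potentials mV, capacitance uF/cm^2, time ms,
# calcium uM.  Kinetic forms live in pcspectra.model; this file fixes the
# numbers so the parameter choice is explicit and swappable.
g_naf: 35.0      # fast sodium
g_kdr: 9.0       # delayed-rectifier potassium
g_cap: 0.05      # P-type calcium (high-threshold, spike calcium source)
g_cat: 1.0       # T-type calcium (slow inactivation paces bursts)
g_kc: 7.0        # BK calcium-activated potassium
g_k2: 0.3        # K2 calcium-activated potassium (slow AHP)
g_leak: 0.15
e_na: 55.0
e_k: -90.0
e_ca: 120.0
e_leak: -60.0
cm: 1.0
ca_alpha: 0.002    # uM*cm^2/(ms*uA): calcium influx per unit Ca current
ca_tau: 12.0     # ms, calcium removal time constant
ca_rest: 0.05    # uM
kd_kc: 1.0       # uM, half-activation of BK by calcium
kd_k2: 0.4       # uM, half-activation of K2 by calcium
noise_sd: 0.02   # uA/cm^2 per sqrt(ms), seeded membrane current noise
v0: -68.0        # mV, initial membrane potential
dt: 0.00625        # ms
duration: 5000.0 # ms
seed: 0
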