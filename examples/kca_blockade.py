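"""Blocking calcium-activated potassium channels in the reduced PC model.

Simulates the single-compartment Purkinje-cell model at rest (no stimulus),
then with the BK-type (KC) and K2 conductances set to zero, and compares
firing and the band-energy profile of the two voltage traces.
"""

from dataclasses import replace

from pcspectra import ModelConfig, count_spikes, simulate, trace_band_profile

cfg = replace(ModelConfig.default(), duration=8000.0)
fs = int(round(1000.0 / cfg.dt))

for label, c in (
    ("baseline", cfg),
    ("KCa blocked", replace(cfg, g_kc=0.0, g_k2=0.0)),
):
    tr = simulate(c)
    prof = trace_band_profile(tr)  # discards the first second, then PSD + bands
    rate = count_spikes(tr.v[-fs:])
    print(f"{label}:")
    print(f"  spike upstrokes in final second: {rate}")
    print(f"  energy in 0-10 Hz             : {100 * prof.fractions[0]:.1f} %")
    print(f"  energy in 10-20 Hz            : {100 * prof.fractions[1]:.1f} %\n")

print("With KC and K2 removed the deep spike afterhyperpolarisation is lost,")
print("fast regular sodium firing gives way to slow calcium-driven bursting:")
print("the spectral energy moves into the 0-10 Hz band, the same low-frequency")
print("shift that distinguishes ataxic from normal cells.")
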