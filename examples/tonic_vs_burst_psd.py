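"""Spectral fingerprints of the two Purkinje-cell firing modes.

Generates one tonic (sodium-spiking) and one bursting (calcium-paced)
surrogate cell, runs each through the full spectral stage and prints the
detected fundamental, the pruned harmonics and the low-band energy.
"""

from pcspectra import BurstParams, TonicParams, generate_burst, generate_tonic, run_cell

for rec in (
    generate_tonic(TonicParams(f_na=22.53, seed=0)),
    generate_burst(BurstParams(f_ca=5.3, seed=0)),
):
    row = run_cell(rec)
    print(f"{rec.mode} cell (target {rec.meta['f_target']:.2f} Hz):")
    print(f"  detected fundamental : {row['peak_freq_hz']:.2f} Hz -> {row['band']} band")
    print(f"  peaks found/retained : {row['n_peaks']}/{row['n_fundamentals']} "
          "(harmonics of the fundamental are pruned)")
    print(f"  energy in 0-10 Hz    : {100 * row['e_0_10']:.1f} % of total\n")

print("A tonic cell concentrates its energy at the sodium-spike rate and its")
print("harmonics (>10 Hz); a bursting cell carries most energy below 10 Hz,")
print("which is what separates the two modes in the band-energy profile.")
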