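"""Solution chemistry: net charge, buffer ionic strength, Debye length, dn/dc.

Computes the pH-dependent net charge of the bundled synthetic stand-in
sequence, speciates the 20 mM sodium-phosphate buffer, and fits dn/dc to
a simulated refractometry series.
"""

from micellab import (
    debye_length,
    fit_dndc,
    ionic_strength,
    net_charge,
    phosphate_speciation,
    simulate_refractometry,
    synthetic_jb6b_sequence,
)

seq = synthetic_jb6b_sequence()  # synthetic stand-in, not the real chaperone
for ph in (2.0, 4.0, 6.0, 8.0):
    print(f"net charge at pH {ph:.0f}: {net_charge(seq, ph):+.1f} e")

species = phosphate_speciation(20.0, 8.0)
i_mm = ionic_strength(species)
print(f"\n20 mM phosphate buffer at pH 8.0: I = {i_mm:.1f} mM")
print(f"Debye length in that buffer: {debye_length(i_mm):.2f} nm")
print(f"Debye length at 1 M 1:1 salt: {debye_length(1000.0):.2f} nm")

fit = fit_dndc(simulate_refractometry(dndc=0.17, seed=8))
print(f"\nfitted dn/dc: {fit.dndc:.3f} ml/g (R^2 = {fit.r_squared:.4f})")
print("A dn/dc matching the calibration standards is what licenses reading")
print("single-particle scattering contrast as particle mass.")
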