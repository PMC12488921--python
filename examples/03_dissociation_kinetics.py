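"""Dissociation kinetics: exponential decays and the Arrhenius barrier.

Simulates triplicate mean-radius time courses at seven temperatures
between 22 and 40 °C, fits each to a single exponential, and extracts
the activation energy of micelle dissociation from the Arrhenius plot.
"""

from micellab import (
    KineticParams,
    arrhenius_from_series,
    rate_and_timescale,
    simulate_dissociation,
)

kparams = KineticParams()  # Ea = 250 kJ/mol, 1/k = 20 min at 37 C
series = simulate_dissociation(
    kparams,
    temperatures_k=[t + 273.15 for t in (22, 25, 28, 31, 34, 37, 40)],
    replicates=3,
    seed=5,
)
fit = arrhenius_from_series(series)
print(f"fitted activation energy: {fit.Ea:.0f} +/- {fit.se_Ea:.0f} kJ/mol")

for t_c in (37.0, 22.0):
    k, tau = rate_and_timescale(fit, t_c + 273.15)
    print(f"at {t_c:.0f} C: k = {k:.2e} 1/s, timescale 1/k = {tau/3600:.2f} h")
print("The ~140-fold rate change over 15 C reflects the high barrier separating")
print("micelles from free monomers: minutes at body temperature, days at the bench.")
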