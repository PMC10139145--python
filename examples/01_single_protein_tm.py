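"""Simulate each core tear protein alone and recover its melting temperature.

Each protein is simulated as a noiseless two-state unfolder on the 35-95 degC
scan; the apex of d(F350/F330)/dT, found via the six-curve path, should land
on the protein's configured Tm to 0.1 degC.
"""

from tfdp import simulate_scan, single_species_mixture, six_curves, species_library
from tfdp.features import detect_peaks

print(f"{'species':8s} {'Tm (model)':>10s} {'Tm (detected)':>14s}")
for name, species in species_library().items():
    run = simulate_scan(single_species_mixture(name), noise_sigma_rel=0.0)
    pk = detect_peaks(six_curves(run))
    detected = pk.t1m if pk.t1m is not None else pk.t2m
    print(f"{name:8s} {species.tm_celsius:10.1f} {detected:14.1f}")

print(
    "\nEach detected apex is the derivative-peak melting temperature; agreement"
    "\nwith the model Tm validates the forward-simulation + detection round trip."
)
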