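"""Tear-protein mixture profiles for healthy and glaucomatous compositions.

The CONTROL preset (140 ug/mL HSA, 110 LTF, 50 LYZ, 30 IgA, 100 LCN1) and the
POAG preset (110/150/30/30/60) are simulated noiselessly; linear superposition
of the five two-state unfolders produces a two-peak profile: a low-Tm apex
from LYZ/LCN1/LTF and a high-Tm apex from HSA/IgA.
"""

from tfdp import mixture_preset, simulate_scan, six_curves
from tfdp.features import detect_peaks

for preset in ("CONTROL", "POAG"):
    run = simulate_scan(mixture_preset(preset), noise_sigma_rel=0.0)
    pk = detect_peaks(six_curves(run))
    print(
        f"{preset:8s}: T1m = {pk.t1m:.1f} degC, T2m = {pk.t2m:.1f} degC "
        f"({pk.n_raw_peaks} qualifying peaks)"
    )

run = simulate_scan(mixture_preset("CONTROL", ligands=["MYRISTATE"]), noise_sigma_rel=0.0)
pk = detect_peaks(six_curves(run))
print(f"CONTROL + myristate: T1m = {pk.t1m:.1f}, T2m = {pk.t2m:.1f} degC")

print(
    "\nThe two apexes are the (T1m, T2m) biomarker pair. Under this linear"
    "\nmodel mixture peaks stay within the span of the component Tms;"
    "\nemergent peak shifts beyond any component Tm, as seen in measured"
    "\ntear fluid, are deliberately out of the model's scope."
)
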