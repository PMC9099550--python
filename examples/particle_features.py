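"""Nanoparticle size-distribution features for the two transport groups.

Builds one binned distribution per group (the pneumatic-tube group is
configured wider and peaking larger, as seen in platelet-free plasma) and
prints the extracted features: total concentration (AUC), spread,
skewness, mode/median size, and the dilution-corrected particle volume.
"""

from cevtransport import particles as pt
from cevtransport import synth

cfg = synth.SyntheticConfig()
for label, params in (("carrier", cfg.particles_c), ("pneumatic tube", cfg.particles_pts)):
    dist = synth.gen_size_distribution(params, seed=2)
    f = pt.distribution_features(dist)
    print(f"--- {label} ---")
    print(f"  AUC (total concentration): {f.auc:.2e} particles/mL")
    print(f"  mode / median size: {f.mode_size:.0f} / {f.median_size:.0f} nm")
    print(f"  width (SD): {f.sd_size:.0f} nm, skewness {f.skewness:.2f}")
    print(f"  original particle volume: {f.original_particle_volume:.2e} nm^3/mL")
print("A wider, larger-peaking distribution raises the particle volume —")
print("the feature that tracks transport harshness in the correlation step.")
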