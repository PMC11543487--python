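"""Sigma-profile mixture descriptors for a DES dilution series.

Builds the ten region areas S1mix..S10mix for choline chloride:glycerol
(1:2) at increasing water content, using the built-in three-peak component
profiles. Region 1 is the most negative sigma (strong hydrogen-bond-donor
surface), region 10 the most positive (strong acceptor surface).
"""

from descreen.sigma_descriptors import (
    MixtureComposition, mix_profiles, mole_fractions, region_areas,
)
from descreen.synthetic_data import sigma_preset

profiles = {
    "choline chloride": sigma_preset("chcl_like"),
    "glycerol": sigma_preset("glycerol_like"),
    "water": sigma_preset("water"),
}

header = "water w/w " + " ".join(f"S{i + 1:<4}" for i in range(10))
print(header)
for w in (0.1, 0.5, 0.8, 0.9):
    comp = MixtureComposition("choline chloride", "glycerol", (1, 2), w)
    fracs = mole_fractions(comp)
    mixed = mix_profiles(profiles, fracs)
    d = region_areas(mixed)
    print(f"{w:9.0%} " + " ".join(f"{v:5.2f}" for v in d.s_mix))

# Dilution pulls every descriptor toward water's own region areas; the
# glycerol-rich mixtures keep the heavier donor-side (low-region) tails.
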