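"""Simulate a radial vs a disorganised microtubule network and measure DoR.

The Degree of Radiality (DoR) compares, per concentric radial section of
the cell, how much the local filament orientations align with the radial
versus the circular direction about the cell center.  DoR > 1 means a
radial, organised network (a polarised synapse); DoR < 1 a tangential
one; DoR = 1 no preference.
"""

from synapsekit import SyntheticCellSpec, dor_at, dor_profile, make_filament_cell

for label, alpha in [("radial (healthy-like)", 1.0), ("disorganised", 0.2)]:
    spec = SyntheticCellSpec(radiality_alpha=alpha, seed=42)
    image, truth = make_filament_cell(spec)
    profile = dor_profile(image, cell_id=label)
    print(f"\n{label}: radiality mixing alpha = {alpha}")
    print(profile.to_frame().to_string(index=False))
    print(f"DoR at relative radial distance 2: {dor_at(profile, 2.0):.2f}")

print(
    "\nThe radial cell scores DoR well above 1 in the interior sections;"
    "\nthe disorganised cell stays near or below 1 at every distance."
)
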