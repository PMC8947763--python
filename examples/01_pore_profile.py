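"""Pore radius profile of a channel with a known 1 A constriction.

Builds a C4 tetramer whose gate ring encloses an inscribed sphere of
exactly 1.0 A radius (the published closed-state gate radius at Ile4937),
then measures it back with the HOLE-style profiler.
"""

from tetrapore import (DomainDefinition, compute_channel_frame,
                       compute_pore_profile, gate_diameter_calpha,
                       radius_at_landmark)
from tetrapore.synthetic import PoreFixtureSpec, build_c4_pore_fixture

model = build_c4_pore_fixture(PoreFixtureSpec(gate_radius=1.0))
frame = compute_channel_frame(model)
profile = compute_pore_profile(model, frame,
                               selection=DomainDefinition("rings",
                                                          ((4930, 4945),)))

print(f"profile: {profile.n_samples} samples, step {profile.step} A")
print(f"minimal pore radius: {profile.min_radius:.3f} A  (built as 1.000)")
print(f"radius at the Ile4937 gate landmark: "
      f"{radius_at_landmark(profile, 4937):.3f} A")
print(f"Calpha gate diameter (mean of diagonals): "
      f"{gate_diameter_calpha(model, 4937, frame):.2f} A")
# The minimal radius is the largest sphere that fits between the van der
# Waals surfaces of the gate ring; a dehydrated Ca2+ ion (~1 A) just fits.
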