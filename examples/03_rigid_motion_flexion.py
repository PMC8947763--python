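"""In-plane/out-of-plane rotation recovery and the flexion angle.

A domain is displaced by a known 3.4 deg twist about the channel axis
plus a 6.8 deg swing about a perpendicular axis; the swing-twist
decomposition recovers both.  The flexion angle of a shell built at
-4.6 deg (the inactivated-state value) is measured back exactly.
"""

from tetrapore import DomainDefinition, domain_motion, flexion_angle
from tetrapore.synthetic import apply_rigid_motion, build_flexion_fixture

base = build_flexion_fixture(0.0)
markers = DomainDefinition("markers", ((348, 348), (984, 984)))
frame_sel = DomainDefinition("rest", ((4800, 5100),))

moved = apply_rigid_motion(base, markers, twist_deg=3.4, swing_deg=6.8,
                           swing_axis_azimuth_deg=60.0)
m = domain_motion(base, moved, markers, frame_selection=frame_sel)
print(f"recovered twist (in-plane): {m.twist_deg:+.3f} deg (built as +3.4)")
print(f"recovered swing (out-of-plane): {m.swing_deg:.3f} deg (built as 6.8)")
print(f"swing direction: {'upward' if m.swing_sign > 0 else 'downward'}")

flex = flexion_angle(build_flexion_fixture(-4.6))
print(f"flexion angle: {flex.mean:+.3f} deg per protomer "
      f"{tuple(round(v, 3) for v in flex.per_protomer)}")
# Negative flexion = the shell periphery bends toward the membrane, the
# signature of channel opening (and, more extremely, of inactivation).
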