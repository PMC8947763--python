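"""Salt bridges, disulfides, ion coordination and surface areas.

Residue pairs are placed at controlled side-chain distances; the
detectors must respect the published cutoffs exactly (3.5 A salt bridge,
2.5 A disulfide, 2.8 A coordination).
"""

import numpy as np

from tetrapore import (compute_sasa, coordination_shell, find_disulfides,
                       find_salt_bridges)
from tetrapore.synthetic import (build_conformation_fixture,
                                 build_interaction_fixture)

fixture = build_interaction_fixture([
    ("GLU", "ARG", 3.4, False),   # inside the 3.5 A cutoff -> detected
    ("GLU", "ARG", 3.6, False),   # outside -> ignored
    ("CYS", "CYS", 2.05, True),   # canonical S-S bond length
])
for r in find_salt_bridges(fixture):
    print(f"salt bridge {r.partner_a[3]}{r.partner_a[2]}-"
          f"{r.partner_b[3]}{r.partner_b[2]} at {r.distance:.2f} A "
          f"(inter-subunit: {r.inter_subunit})")
for r in find_disulfides(fixture):
    print(f"disulfide at {r.distance:.2f} A")

inact = build_conformation_fixture(ca_ion=True, salt_bridges=True)
print(f"inter-subunit bridges in the inactivated mimic: "
      f"{len(find_salt_bridges(inact, scope='inter_subunit'))} (2 pairs x C4)")
ion, shell = coordination_shell(inact, "CA")[0]
print("Ca2+ coordination shell (<= 2.8 A):",
      sorted({f"{r.partner_b[3]}{r.partner_b[2]}" for r in shell}))

sasa = compute_sasa(inact.subset(~inact.is_hetero))
print(f"protein SASA of the mimic: {sasa.total:.0f} A^2 "
      f"({np.count_nonzero(sasa.per_atom):d} exposed atoms)")
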