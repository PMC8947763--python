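# Example configuration for `tetrapore --config`.
#
# [domains] entries extend or override the built-in registry (author
# residue numbering, inclusive intervals).  The central-block
# subdivisions U_motif / S6N / S6C have no built-in boundaries and must
# be supplied here before heatmaps or motions can reference them.

[domains]
U_motif = { ranges = [[4071, 4080], [4124, 4253]] }
S6N = { ranges = [[4894, 4920]] }
S6C = { ranges = [[4921, 4956]] }

[analysis]
salt_bridge_cutoff = 3.5
coordination_cutoff = 2.8
polar_contact_cutoff = 3.6
ligand_contact_cutoff = 4.0
lipid_contact_cutoff = 5.0
pore_step = 0.25
pore_max_radius = 15.0
rpt_window = 3

[analysis.vdw_radii]
C = 1.85
N = 1.75
O = 1.65
S = 2.00
H = 1.00
P = 2.10
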