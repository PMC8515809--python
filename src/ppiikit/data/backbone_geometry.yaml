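# Default backbone internal-coordinate table (standard peptide values).
# Lengths in Å, angles in degrees. Users may supply their own table with
# the same keys to ppiikit.backbone_geometry.GeometryTable.from_file.
bond_lengths:
  N-CA: 1.458
  CA-C: 1.525
  C-N: 1.329
  C-O: 1.229
bond_angles:
  N-CA-C: 111.0
  CA-C-N: 116.2
  C-N-CA: 121.7
  CA-C-O: 120.5
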