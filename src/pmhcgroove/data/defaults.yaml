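# Canonical analysis profile: the conventions every stage defaults to.
selections:
  binding_site:
    A: [5, 76]
    B: [5, 90]
  compartments:
    - [D1, [50, 51], [85, 86]]
    - [D2, [53, 55], [78, 83]]
    - [D3, [60, 65], [65, 70]]
    - [D4, [68, 73], [56, 61]]
criteria:
  hbond: {da_cutoff: 3.1, angle_cutoff: 130.0, persistence_threshold: 0.2}
  stacking: {dihedral_cutoff: 30.0, centroid_cutoff: 5.0, persistence_threshold: 0.2}
  hydrophobic: {contact_cutoff: 4.0, water_exclusion_radius: 4.0, persistence_threshold: 0.2}
sie:
  alpha: 0.1048
  d_in: 2.25
  gamma: 0.0129
  constant: -2.89
  temperature: 310.0
  stride_ps: 20.0
entropy:
  temperature: 310.0
histograms:
  rmsd_bin_width: 0.1
  distance_bin_width: 0.25
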