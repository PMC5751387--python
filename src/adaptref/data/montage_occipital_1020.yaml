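# 13-electrode occipito-parietal montage (international 10-20 system) used for
# SSVEP work. Positions are the standard spherical-head projection, in
# centimetres. Filter targets are the occipital electrodes O1, O2, Oz.
name: occipital_1020
reference_note: vertex reference, ground midway between Fz and FPz
electrodes:
  O1: [-2.941, -11.245, 0.884]
  O2: [2.984, -11.216, 0.880]
  Oz: [0.011, -11.489, 1.466]
  PO3: [-3.651, -10.085, 3.717]
  PO4: [3.678, -10.085, 3.640]
  PO7: [-5.484, -9.753, 0.279]
  PO8: [5.567, -9.763, 0.273]
  POz: [0.022, -10.218, 5.061]
  P1: [-2.862, -8.052, 7.544]
  P2: [3.192, -8.049, 7.672]
  P3: [-5.301, -7.879, 5.594]
  P4: [5.567, -7.856, 5.656]
  Pz: [0.032, -8.111, 8.261]
targets: [O1, O2, Oz]
neighbors_small:
  O1: [Oz, PO7, PO3]
  O2: [Oz, PO8, PO4]
  Oz: [O1, O2, POz]
neighbors_large:
  O1: [O2, POz, P3]
  O2: [O1, POz, P4]
  Oz: [PO3, PO4, PO7, PO8]
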