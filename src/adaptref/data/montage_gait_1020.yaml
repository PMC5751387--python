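# 20-electrode motor-cortex montage (international 10-20 system) for gait-planning
# recording around the primary and supplementary motor areas. Positions are the
# standard spherical-head projection of the 10-20 layout, in centimetres.
# Filter targets are Cz, CP1 and CP2. The WAR surround is listed explicitly
# (neighbors_war); the LAR rings split the six surrounding locations
# {FCz, C1, C2, CPz, CP3, CP4} by geometric proximity to each target.
name: gait_1020
reference_note: earlobe reference (A1/A2), ground between the eyebrows
electrodes:
  FC3: [-6.018, 2.272, 5.554]
  FC1: [-3.406, 2.601, 7.999]
  FCz: [0.038, 2.739, 8.867]
  FC2: [3.478, 2.644, 7.881]
  FC4: [6.229, 2.372, 5.563]
  C5: [-8.028, -1.376, 2.916]
  C3: [-6.536, -1.163, 6.436]
  C1: [-3.616, -0.998, 8.975]
  Cz: [0.040, -0.917, 10.024]
  C2: [3.767, -0.962, 8.841]
  C4: [6.712, -1.090, 6.358]
  C6: [8.346, -1.278, 2.921]
  CP5: [-7.959, -4.655, 3.095]
  CP3: [-6.356, -4.701, 6.562]
  CP1: [-3.551, -4.729, 9.131]
  CPz: [0.039, -4.732, 9.943]
  CP2: [3.838, -4.707, 9.069]
  CP4: [6.661, -4.664, 6.558]
  CP6: [8.332, -4.610, 3.121]
  Pz: [0.032, -8.111, 8.261]
targets: [Cz, CP1, CP2]
neighbors_small:
  Cz: [C1, CPz, FCz]
  CP1: [CPz, C1, CP3]
  CP2: [CPz, C2, CP4]
neighbors_large:
  Cz: [C2, CP3, CP4]
  CP1: [C2, FCz, CP4]
  CP2: [C1, FCz, CP3]
neighbors_war:
  Cz: [FC3, FC1, C3, C4, Pz]
  CP1: [FC3, FC1, C3, C4, Pz]
  CP2: [FC3, FC1, C3, C4, Pz]
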