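# Acadian-region edatopic grid: 10 combined ecosites tiling the
# SNR (horizontal, [0,5]) x SMR (vertical, [0,7]) domain.
#
# SYNTHETIC approximation: the published figure's ellipse and rectangle
# coordinates are not tabulated anywhere in text form, so these rectangles
# were generated from the transform procedure applied to the packaged
# ellipse approximation and synthetic plots, then hand-adjusted to honour
# the two published worked-example constraints (a plot at SNR 0.5 falls in
# ecosite 2 at SMR 3.6 and in ecosite 3 at SMR 3.4, i.e. the 2/3 boundary
# sits at SMR 3.5) and the qualitative layout (ecosites 5 and 6 central;
# 1, 3, 7 and 10 peripheral).
region: acadian
domain:
  snr: [0.0, 5.0]
  smr: [0.0, 7.0]
rectangles:
  - {id: 1, snr: [0.0, 1.0], smr: [5.0, 7.0]}   # jack pine - black spruce; dry, very poor
  - {id: 2, snr: [0.0, 1.0], smr: [3.5, 5.0]}   # black spruce - pine; fresh, very poor
  - {id: 3, snr: [0.0, 1.0], smr: [2.0, 3.5]}   # black spruce - pine; moist, very poor
  - {id: 4, snr: [0.0, 2.5], smr: [0.0, 2.0]}   # black spruce - tamarack; wet, poor
  - {id: 5, snr: [1.0, 2.5], smr: [2.0, 4.5]}   # red spruce - hemlock; central
  - {id: 6, snr: [2.5, 3.5], smr: [2.0, 4.5]}   # black spruce - white pine; central
  - {id: 7, snr: [3.5, 5.0], smr: [2.0, 4.5]}   # sugar maple - yellow birch; rich
  - {id: 8, snr: [1.0, 3.0], smr: [4.5, 7.0]}   # sugar maple - white ash; dry, medium
  - {id: 9, snr: [3.0, 5.0], smr: [4.5, 7.0]}   # sugar maple - white ash; dry, rich
  - {id: 10, snr: [2.5, 5.0], smr: [0.0, 2.0]}  # white ash - red maple; wet, rich
ellipses:
  - {id: 1, center: [0.5, 5.4], semi_axes: [0.45, 0.6]}
  - {id: 5, center: [0.5, 6.0], semi_axes: [0.45, 0.6]}
  - {id: 9, center: [0.5, 6.6], semi_axes: [0.45, 0.6]}
  - {id: 2, center: [0.5, 3.9], semi_axes: [0.45, 0.55]}
  - {id: 6, center: [0.5, 4.6], semi_axes: [0.45, 0.55]}
  - {id: 3, center: [0.5, 2.75], semi_axes: [0.45, 0.7]}
  - {id: 4, center: [0.8, 1.0], semi_axes: [0.7, 0.9]}
  - {id: 8, center: [1.7, 1.0], semi_axes: [0.7, 0.9]}
  - {id: 10, center: [1.75, 2.7], semi_axes: [0.65, 0.75]}
  - {id: 13, center: [1.75, 3.9], semi_axes: [0.65, 0.75]}
  - {id: 7, center: [3.0, 2.7], semi_axes: [0.45, 0.75]}
  - {id: 11, center: [3.0, 3.9], semi_axes: [0.45, 0.75]}
  - {id: 14, center: [4.25, 2.7], semi_axes: [0.65, 0.75]}
  - {id: 12, center: [4.25, 3.9], semi_axes: [0.65, 0.75]}
  - {id: 16, center: [2.0, 5.75], semi_axes: [0.9, 1.1]}
  - {id: 17, center: [4.0, 5.75], semi_axes: [0.9, 1.1]}
  - {id: 15, center: [3.75, 1.0], semi_axes: [1.1, 0.9]}
combination_rules:
  1: {combined: 1, condition: 1}
  5: {combined: 1, condition: 1}
  9: {combined: 1, condition: 1}
  2: {combined: 2, condition: 2}
  6: {combined: 2, condition: 2}
  3: {combined: 3}
  4: {combined: 4, condition: 3}
  8: {combined: 4, condition: 3}
  10: {combined: 5, condition: 2}
  13: {combined: 5, condition: 2}
  7: {combined: 6, condition: 3}
  11: {combined: 6, condition: 3}
  14: {combined: 7, condition: 3}
  12: {combined: 7, condition: 3}
  16: {combined: 8}
  17: {combined: 9}
  15: {combined: 10}
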