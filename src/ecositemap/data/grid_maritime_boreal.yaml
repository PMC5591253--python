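# Maritime-Boreal-region edatopic grid: 10 combined ecosites (from 11
# originals) tiling SNR [0,5] x SMR [0,7].
#
# SYNTHETIC approximation — see grid_acadian.yaml for provenance; the same
# construction and caveats apply (published figure coordinates are not
# available in text form).
region: maritime_boreal
domain:
  snr: [0.0, 5.0]
  smr: [0.0, 7.0]
rectangles:
  - {id: 1, snr: [0.0, 1.5], smr: [5.0, 7.0]}   # black spruce - jack pine; dry, poor
  - {id: 2, snr: [0.0, 1.5], smr: [0.0, 1.5]}   # black spruce; wet, poor
  - {id: 3, snr: [0.0, 1.5], smr: [1.5, 3.5]}   # black spruce; moist, poor
  - {id: 4, snr: [0.0, 1.5], smr: [3.5, 5.0]}   # black spruce; fresh, poor
  - {id: 5, snr: [1.5, 3.0], smr: [0.0, 2.5]}   # fir - spruce; wet, medium
  - {id: 6, snr: [1.5, 3.0], smr: [2.5, 4.5]}   # fir - spruce; central
  - {id: 7, snr: [1.5, 3.0], smr: [4.5, 7.0]}   # red maple - fir; dry, medium
  - {id: 8, snr: [3.0, 5.0], smr: [4.5, 7.0]}   # birch - fir; dry, rich
  - {id: 9, snr: [3.0, 5.0], smr: [2.5, 4.5]}   # red maple; rich
  - {id: 10, snr: [3.0, 5.0], smr: [0.0, 2.5]}  # red maple - birch; wet, rich
ellipses:
  - {id: 1, center: [0.75, 6.0], semi_axes: [0.65, 0.9]}
  - {id: 2, center: [0.75, 0.75], semi_axes: [0.65, 0.65]}
  - {id: 3, center: [0.75, 2.5], semi_axes: [0.65, 0.9]}
  - {id: 4, center: [0.75, 4.25], semi_axes: [0.65, 0.65]}
  - {id: 5, center: [2.25, 1.25], semi_axes: [0.65, 1.1]}
  - {id: 6, center: [2.25, 3.5], semi_axes: [0.65, 0.9]}
  - {id: 7, center: [2.25, 5.75], semi_axes: [0.65, 1.1]}
  - {id: 8, center: [3.7, 5.75], semi_axes: [0.8, 1.0]}
  - {id: 9, center: [4.4, 5.75], semi_axes: [0.8, 1.0]}
  - {id: 10, center: [4.0, 3.5], semi_axes: [0.9, 0.9]}
  - {id: 11, center: [4.0, 1.25], semi_axes: [0.9, 1.1]}
combination_rules:
  1: {combined: 1}
  2: {combined: 2}
  3: {combined: 3}
  4: {combined: 4}
  5: {combined: 5}
  6: {combined: 6}
  7: {combined: 7}
  8: {combined: 8, condition: 2}
  9: {combined: 8, condition: 2}
  10: {combined: 9}
  11: {combined: 10}
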