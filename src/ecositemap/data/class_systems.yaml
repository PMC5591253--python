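# Ordinal class systems used in Nova Scotia forest ecosystem classification.
# Class order runs wettest/poorest -> driest/richest; midpoints are the
# continuous class-unit codings (half classes sit at the integers between
# adjacent full-class midpoints, e.g. very poor/poor = 1.0).
systems:
  - name: drainage
    classes:
      - very poor
      - poor
      - imperfect
      - moderately well
      - well
      - rapidly
      - very rapidly
    midpoints: [0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5]
    range: [0.0, 7.0]
    supports_half_classes: true
  - name: smr
    classes:
      - wet
      - moist/wet
      - moist
      - fresh/moist
      - fresh
      - dry
      - very dry
    midpoints: [0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5]
    range: [0.0, 7.0]
    supports_half_classes: true
  - name: snr
    classes:
      - very poor
      - poor
      - medium
      - rich
      - very rich
    midpoints: [0.5, 1.5, 2.5, 3.5, 4.5]
    range: [0.0, 5.0]
    supports_half_classes: true
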