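# Published per-ecoregion linear calibrations converting model-predicted
# continuous soil drainage (SD, class units) into continuous soil moisture
# regime (SMR, class units):
#   Acadian:          SMR = 0.1997 + 0.9869 * SD   (r^2 = 0.88, n = 1384)
#   Maritime-Boreal:  SMR = 0.2683 + 0.9500 * SD   (r^2 = 0.89, n = 123)
# The SNR ~ clay calibration was never published in equation form; fit your
# own with `ecositemap calibrate` or supply coefficients via this schema.
calibrations:
  - region: acadian
    response: smr
    predictor: drainage
    intercept: 0.1997
    slope: 0.9869
    r_squared: 0.88
    n: 1384
  - region: maritime_boreal
    response: smr
    predictor: drainage
    intercept: 0.2683
    slope: 0.9500
    r_squared: 0.89
    n: 123
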