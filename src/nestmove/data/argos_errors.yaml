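# Per-class Argos location error, one sd in km per planar coordinate.
# Values are the one-sd errors of Vincent et al. (2002), the calibration
# underlying the class-specific measurement model of Jonsen et al. (2005).
# These are configuration, not constants: replace with your own calibration
# if available.
sd_km:
  "3": 0.49
  "2": 1.01
  "1": 1.20
  "0": 4.18
  "A": 6.19
  "B": 10.28
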