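The plant is at the tillering stage and appears diseased.
Leaf area is 52.10 cm^2.
Canopy area is 48.00 cm^2.
Plant height is 41.24 cm.
Constraint violation: leaf area (52.10 cm^2) exceeds canopy area (48.00 cm^2).
Environment: mean temperature 26.30 degC, humidity 72.50 %, soil moisture 14.80 g/cm^3, par 1050.00 umol m^-2 s^-1.
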