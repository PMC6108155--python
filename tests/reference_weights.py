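"""Frozen printed reference values for the default stepped weight tables.

Independently verified 3-decimal weights for the default car scheme
(30-min catchment, sub-zone means 5/15/25) over betas 140..320 step 15,
and the default bus scheme (60-min catchment, sub-zone means 5/15/25/45)
over betas 440..1040 step 50.
"""

# beta -> (weight at 5 min, 15 min, 25 min)
CAR_TABLE = {
    140: (0.836, 0.200, 0.012),
    155: (0.851, 0.234, 0.018),
    170: (0.863, 0.266, 0.025),
    185: (0.874, 0.296, 0.034),
    200: (0.882, 0.325, 0.044),
    215: (0.890, 0.351, 0.055),
    230: (0.897, 0.376, 0.066),
    245: (0.903, 0.399, 0.078),
    260: (0.908, 0.421, 0.090),
    275: (0.913, 0.441, 0.103),
    290: (0.917, 0.460, 0.116),
    305: (0.921, 0.478, 0.129),
    320: (0.925, 0.495, 0.142),
}

# beta -> (weight at 5 min, 15 min, 25 min, 45 min)
BUS_TABLE = {
    440: (0.945, 0.600, 0.242, 0.010),
    490: (0.950, 0.632, 0.279, 0.016),
    540: (0.955, 0.659, 0.314, 0.024),
    590: (0.959, 0.683, 0.347, 0.032),
    640: (0.962, 0.704, 0.377, 0.042),
    690: (0.964, 0.722, 0.404, 0.053),
    740: (0.967, 0.738, 0.430, 0.065),
    790: (0.969, 0.752, 0.453, 0.077),
    840: (0.971, 0.765, 0.475, 0.090),
    890: (0.972, 0.777, 0.495, 0.103),
    940: (0.974, 0.787, 0.514, 0.116),
    990: (0.975, 0.797, 0.532, 0.129),
    1040: (0.976, 0.805, 0.548, 0.143),
}
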