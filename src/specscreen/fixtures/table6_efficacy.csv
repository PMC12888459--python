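group,W/D ratio of Lung,Lung injury score,Neutrophils in BALF,TNF-α,IL-6,IL-1β,Protein in BALF,Overall rating
PW1,4.88,36.05,64.65,65.04,27.13,72.04,36.62,43.35
PW2,6.71,45.35,49.70,80.12,39.66,66.79,32.39,47.17
PW3,6.71,53.49,68.68,55.92,36.13,51.57,29.58,48.24
PW4,8.33,51.16,75.00,58.02,45.17,58.42,33.80,51.46
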