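indicator,weight
W/D ratio of Lung,0.0975
Lung injury score,0.3080
Neutrophils in BALF,0.1845
TNF-α,0.1181
IL-6,0.1842
IL-1β,0.0909
Protein in BALF,0.0168
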