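indicator,peak_id
Lung injury score,A40
Lung injury score,A27
Lung injury score,A11
Lung injury score,B14
Lung injury score,B16
TNF-α,A7
TNF-α,A32
TNF-α,A18
TNF-α,A6
IL-6,A27
IL-6,B16
IL-6,A11
IL-6,A1
IL-6,B17
IL-6,A6
IL-1β,A20
IL-1β,A18
IL-1β,A19
IL-1β,A32
IL-1β,A7
W/D ratio of Lung,B16
W/D ratio of Lung,A11
W/D ratio of Lung,A27
W/D ratio of Lung,A1
W/D ratio of Lung,B17
Protein in BALF,A9
Protein in BALF,A20
Protein in BALF,A19
Protein in BALF,A18
Protein in BALF,A32
Neutrophils in BALF,A24
Neutrophils in BALF,A26
Neutrophils in BALF,A30
Neutrophils in BALF,A34
Neutrophils in BALF,A17
Neutrophils in BALF,B11
Overall rating,A11
Overall rating,B16
Overall rating,A27
Overall rating,A1
Overall rating,B17
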