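peak_id,betweenness,closeness,degree,herb,median_flag
A1,0.0155,0.3625,4,GF,0
A6,0.0331,0.3718,3,SR,0
A7,0.0535,0.3816,3,SR,1
A9,0.0361,0.3718,2,SR,0
A11,0.0321,0.3816,5,GF,1
A17,0.0082,0.3625,2,SR,0
A18,0.0478,0.4028,4,GF,1
A19,0.0213,0.3816,3,SR,0
A20,0.0213,0.3816,3,SR,0
A24,0.0082,0.3625,2,SR,0
A26,0.0082,0.3625,2,SR,0
A27,0.1878,0.4531,5,GF,1
A30,0.0082,0.3625,2,SR,0
A32,0.0478,0.4028,4,SR,1
A34,0.0082,0.3625,2,GF,0
A40,0.0305,0.3816,2,GF,1
B11,0.0611,0.3816,2,GF,1
B14,0.0081,0.3537,2,GF,0
B16,0.0321,0.3816,5,GF,1
B17,0.0155,0.3625,4,GF,0
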