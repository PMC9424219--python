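neurons,tanh,sigmoid,relu
10,47.9,74.2,93.7
20,42.1,75.6,99.9
30,51.1,79.5,98.0
40,45.6,79.4,97.4
50,53.2,84.6,97.4
60,52.1,85.8,98.6
70,49.1,81.1,99.3
80,54.1,83.7,99.4
90,50.9,82.6,98.7
100,53.9,86.0,99.7
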