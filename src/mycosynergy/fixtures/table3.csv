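concentration,germination_pct,vegetative_growth_mm,conidiation
0,98.9,86.6,7.9
0.7,98.0,85.4,7.2
1.4,97.6,83.1,6.7
2.1,96.4,80.4,6.4
2.8,95.9,76.8,5.8
3.5,95.2,74.2,5.3
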