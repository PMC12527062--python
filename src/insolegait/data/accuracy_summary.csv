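participant_id,gaitup_right,gaitup_left,approach1_right,approach1_left,approach2_right,approach2_left
P1,97.71,98.49,99.01,98.67,99.79,99.22
P2,97.14,95.85,99.72,97.41,98.33,94.86
P3,97.54,99.06,98.13,98.65,99.40,98.85
P4,97.17,98.43,98.61,99.93,99.21,98.88
P5,98.28,98.70,99.37,97.48,98.30,99.84
P6,95.98,97.07,96.61,99.92,98.49,99.98
P7,99.67,97.16,98.86,99.32,98.73,99.05
P8,97.61,96.57,99.10,97.76,99.47,98.89
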