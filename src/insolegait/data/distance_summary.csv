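participant_id,actual_distance,gaitup_distance_right,gaitup_distance_left,approach1_distance_right,approach1_distance_left,approach2_distance_right,approach2_distance_left
P1,610.88,624.86,620.08,616.93,618.98,612.16,615.66
P2,611.78,629.28,637.17,610.09,627.63,622.00,643.24
P3,543.85,557.21,548.96,554.01,551.20,547.09,550.10
P4,574.94,591.19,583.97,582.92,575.32,579.5,581.36
P5,608.00,618.46,600.1,611.84,592.69,618.34,607.05
P6,743.25,713.4,721.48,718.02,743.81,731.99,743.4
P7,625.54,623.49,643.29,618.41,629.83,617.59,631.48
P8,541.42,554.36,559.99,536.52,553.52,538.56,547.42
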