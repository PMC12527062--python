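participant_id,actual_count,actual_stride_length,gaitup_count_right,gaitup_count_left,gaitup_length_right,gaitup_length_left,insole_count_right,insole_count_left,approach1_length_right,approach1_length_left,approach2_length_right,approach2_length_left
P1,368,1.66,368,368,1.698,1.685,367,368,1.681,1.682,1.668,1.673
P2,362,1.690,360,361,1.748,1.765,361,363,1.690,1.729,1.723,1.772
P3,365,1.490,363,365,1.535,1.504,364,366,1.522,1.506,1.503,1.503
P4,380,1.513,378,377,1.564,1.549,380,387,1.534,1.522,1.525,1.538
P5,341,1.783,340,340,1.819,1.765,342,342,1.789,1.733,1.808,1.775
P6,412,1.804,410,409,1.740,1.764,411,413,1.747,1.801,1.781,1.800
P7,411,1.522,411,410,1.517,1.569,409,413,1.512,1.525,1.510,1.529
P8,408,1.327,402,402,1.379,1.393,408,407,1.315,1.360,1.320,1.345
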