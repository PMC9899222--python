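device,scenario,z_m,average_bq_m3
AlphaGUARD,open,0.2,91
RAD7,open,0.2,87
Raduet,open,0.2,72
NRPB,open,0.2,65
Simulation,open,0.2,93
AlphaGUARD,open,1.0,77
RAD7,open,1.0,81
Raduet,open,1.0,68
NRPB,open,1.0,64
Simulation,open,1.0,82
Raduet,open,1.8,62
NRPB,open,1.8,59
Simulation,open,1.8,95
AlphaGUARD,closed,0.2,86
RAD7,closed,0.2,92
Raduet,closed,0.2,73
NRPB,closed,0.2,68
Simulation,closed,0.2,112
AlphaGUARD,closed,1.0,85
RAD7,closed,1.0,86
Raduet,closed,1.0,80
NRPB,closed,1.0,65
Simulation,closed,1.0,95
Raduet,closed,1.8,73
NRPB,closed,1.8,69
Simulation,closed,1.8,79
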