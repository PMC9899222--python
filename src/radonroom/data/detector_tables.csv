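device,scenario,ach_per_h,point,x_m,y_m,z_m,concentration_bq_m3
AlphaGUARD,open,1.0,A,2.9,0.1,0.2,119
AlphaGUARD,open,1.0,B,0.1,0.1,0.2,112
AlphaGUARD,open,1.0,C,0.1,3.9,0.2,81
AlphaGUARD,open,1.0,D,2.9,3.9,0.2,58
AlphaGUARD,open,1.0,Center,1.5,2.0,0.2,84
RAD7,open,1.0,A,2.9,0.1,0.2,110
RAD7,open,1.0,B,0.1,0.1,0.2,103
RAD7,open,1.0,C,0.1,3.9,0.2,84
RAD7,open,1.0,D,2.9,3.9,0.2,51
RAD7,open,1.0,Center,1.5,2.0,0.2,89
Raduet,open,1.0,A,2.9,0.1,0.2,88
Raduet,open,1.0,B,0.1,0.1,0.2,73
Raduet,open,1.0,C,0.1,3.9,0.2,66
Raduet,open,1.0,D,2.9,3.9,0.2,62
NRPB,open,1.0,A,2.9,0.1,0.2,74
NRPB,open,1.0,B,0.1,0.1,0.2,60
NRPB,open,1.0,C,0.1,3.9,0.2,69
NRPB,open,1.0,D,2.9,3.9,0.2,55
Simulation,open,1.0,A,2.9,0.1,0.2,163
Simulation,open,1.0,B,0.1,0.1,0.2,115
Simulation,open,1.0,C,0.1,3.9,0.2,65
Simulation,open,1.0,D,2.9,3.9,0.2,46
Simulation,open,1.0,Center,1.5,2.0,0.2,76
AlphaGUARD,open,1.0,A,2.9,0.1,1.0,92
AlphaGUARD,open,1.0,B,0.1,0.1,1.0,102
AlphaGUARD,open,1.0,C,0.1,3.9,1.0,67
AlphaGUARD,open,1.0,D,2.9,3.9,1.0,55
AlphaGUARD,open,1.0,Center,1.5,2.0,1.0,70
RAD7,open,1.0,A,2.9,0.1,1.0,109
RAD7,open,1.0,B,0.1,0.1,1.0,93
RAD7,open,1.0,C,0.1,3.9,1.0,71
RAD7,open,1.0,D,2.9,3.9,1.0,58
RAD7,open,1.0,Center,1.5,2.0,1.0,74
Raduet,open,1.0,A,2.9,0.1,1.0,66
Raduet,open,1.0,B,0.1,0.1,1.0,83
Raduet,open,1.0,C,0.1,3.9,1.0,61
Raduet,open,1.0,D,2.9,3.9,1.0,63
NRPB,open,1.0,A,2.9,0.1,1.0,71
NRPB,open,1.0,B,0.1,0.1,1.0,69
NRPB,open,1.0,C,0.1,3.9,1.0,59
NRPB,open,1.0,D,2.9,3.9,1.0,56
Simulation,open,1.0,A,2.9,0.1,1.0,154
Simulation,open,1.0,B,0.1,0.1,1.0,98
Simulation,open,1.0,C,0.1,3.9,1.0,50
Simulation,open,1.0,D,2.9,3.9,1.0,52
Simulation,open,1.0,Center,1.5,2.0,1.0,57
Raduet,open,1.0,A,2.9,0.1,1.8,65
Raduet,open,1.0,B,0.1,0.1,1.8,68
Raduet,open,1.0,C,0.1,3.9,1.8,55
Raduet,open,1.0,D,2.9,3.9,1.8,60
NRPB,open,1.0,A,2.9,0.1,1.8,63
NRPB,open,1.0,B,0.1,0.1,1.8,58
NRPB,open,1.0,C,0.1,3.9,1.8,60
NRPB,open,1.0,D,2.9,3.9,1.8,55
Simulation,open,1.0,A,2.9,0.1,1.8,199
Simulation,open,1.0,B,0.1,0.1,1.8,117
Simulation,open,1.0,C,0.1,3.9,1.8,49
Simulation,open,1.0,D,2.9,3.9,1.8,50
Simulation,open,1.0,Center,1.5,2.0,1.8,61
AlphaGUARD,closed,1.0,A,2.9,0.1,0.2,93
AlphaGUARD,closed,1.0,B,0.1,0.1,0.2,109
AlphaGUARD,closed,1.0,C,0.1,3.9,0.2,74
AlphaGUARD,closed,1.0,D,2.9,3.9,0.2,63
AlphaGUARD,closed,1.0,Center,1.5,2.0,0.2,91.5
RAD7,closed,1.0,A,2.9,0.1,0.2,120
RAD7,closed,1.0,B,0.1,0.1,0.2,99
RAD7,closed,1.0,C,0.1,3.9,0.2,82
RAD7,closed,1.0,D,2.9,3.9,0.2,66
RAD7,closed,1.0,Center,1.5,2.0,0.2,95.8
Raduet,closed,1.0,A,2.9,0.1,0.2,88
Raduet,closed,1.0,B,0.1,0.1,0.2,79
Raduet,closed,1.0,C,0.1,3.9,0.2,58
Raduet,closed,1.0,D,2.9,3.9,0.2,65
NRPB,closed,1.0,A,2.9,0.1,0.2,77
NRPB,closed,1.0,B,0.1,0.1,0.2,65
NRPB,closed,1.0,C,0.1,3.9,0.2,72
NRPB,closed,1.0,D,2.9,3.9,0.2,59
Simulation,closed,1.0,A,2.9,0.1,0.2,224.43
Simulation,closed,1.0,B,0.1,0.1,0.2,133.41
Simulation,closed,1.0,C,0.1,3.9,0.2,68.57
Simulation,closed,1.0,D,2.9,3.9,0.2,54.42
Simulation,closed,1.0,Center,1.5,2.0,0.2,82.35
AlphaGUARD,closed,1.0,A,2.9,0.1,1.0,110
AlphaGUARD,closed,1.0,B,0.1,0.1,1.0,108
AlphaGUARD,closed,1.0,C,0.1,3.9,1.0,61
AlphaGUARD,closed,1.0,D,2.9,3.9,1.0,63
AlphaGUARD,closed,1.0,Center,1.5,2.0,1.0,84.6
RAD7,closed,1.0,A,2.9,0.1,1.0,119
RAD7,closed,1.0,B,0.1,0.1,1.0,105
RAD7,closed,1.0,C,0.1,3.9,1.0,68
RAD7,closed,1.0,D,2.9,3.9,1.0,61
RAD7,closed,1.0,Center,1.5,2.0,1.0,77.1
Raduet,closed,1.0,A,2.9,0.1,1.0,89
Raduet,closed,1.0,B,0.1,0.1,1.0,92
Raduet,closed,1.0,C,0.1,3.9,1.0,66
Raduet,closed,1.0,D,2.9,3.9,1.0,74
NRPB,closed,1.0,A,2.9,0.1,1.0,76
NRPB,closed,1.0,B,0.1,0.1,1.0,66
NRPB,closed,1.0,C,0.1,3.9,1.0,58
NRPB,closed,1.0,D,2.9,3.9,1.0,63
Simulation,closed,1.0,A,2.9,0.1,1.0,170.7
Simulation,closed,1.0,B,0.1,0.1,1.0,140.18
Simulation,closed,1.0,C,0.1,3.9,1.0,51.33
Simulation,closed,1.0,D,2.9,3.9,1.0,45.3
Simulation,closed,1.0,Center,1.5,2.0,1.0,65.59
Raduet,closed,1.0,A,2.9,0.1,1.8,75
Raduet,closed,1.0,B,0.1,0.1,1.8,95
Raduet,closed,1.0,C,0.1,3.9,1.8,64
Raduet,closed,1.0,D,2.9,3.9,1.8,57
NRPB,closed,1.0,A,2.9,0.1,1.8,77
NRPB,closed,1.0,B,0.1,0.1,1.8,80
NRPB,closed,1.0,C,0.1,3.9,1.8,58
NRPB,closed,1.0,D,2.9,3.9,1.8,66
Simulation,closed,1.0,A,2.9,0.1,1.8,110.12
Simulation,closed,1.0,B,0.1,0.1,1.8,121.21
Simulation,closed,1.0,C,0.1,3.9,1.8,52.3
Simulation,closed,1.0,D,2.9,3.9,1.8,46.23
Simulation,closed,1.0,Center,1.5,2.0,1.8,59.17
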