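id,lat,lon,n,males,females
OCA,39.985445,-3.630508,20,12,8
HUE,39.838697,-3.617103,18,15,3
CER,39.694744,-3.301181,20,10,10
ALT,39.703076,-3.302290,20,10,10
LON,39.700548,-3.321046,20,10,10
ALB,39.658024,-3.288700,20,10,10
FAD,39.634933,-3.231576,20,10,10
LAR,39.609088,-3.317164,19,11,8
TIR,39.546603,-3.354411,19,9,10
PEN,39.517720,-3.350181,19,10,9
QUE,39.526984,-3.272089,20,9,11
CAR,39.472016,-3.262528,19,9,10
YEG,39.418396,-3.281576,20,10,10
PAL,39.535906,-3.172344,20,10,10
LAG,39.538542,-3.134392,19,10,9
SCO,39.470083,-3.173809,20,14,6
PED,39.491164,-2.767518,20,17,3
ALC,39.391585,-2.875947,19,15,4
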