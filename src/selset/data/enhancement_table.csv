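electrode,bin,bin_start_ms,bin_end_ms,diff_uv,label,polarity
F3,1,0,100,-0.142,,-1
F3,2,100,200,1.280,T,1
F3,3,200,300,0.809,T,1
F3,4,300,400,-1.198,T,-1
F3,5,400,500,-3.855,T,-1
F3,6,500,600,-2.266,T,-1
F3,7,600,700,-0.686,,-1
Fz,1,0,100,1.298,T,1
Fz,2,100,200,1.997,T,1
Fz,3,200,300,2.275,T,1
Fz,4,300,400,-0.101,,-1
Fz,5,400,500,-0.109,,-1
Fz,6,500,600,-0.876,D,1
Fz,7,600,700,-1.781,D,1
F4,1,0,100,-0.550,,-1
F4,2,100,200,2.962,T,1
F4,3,200,300,-1.617,T,-1
F4,4,300,400,-0.024,,-1
F4,5,400,500,2.493,T,1
F4,6,500,600,1.017,T,1
F4,7,600,700,0.800,T,1
T7,1,0,100,-1.644,T,-1
T7,2,100,200,-4.249,T,-1
T7,3,200,300,0.095,,1
T7,4,300,400,-1.375,T,-1
T7,5,400,500,-0.568,,-1
T7,6,500,600,1.067,T,1
T7,7,600,700,-0.782,,-1
Cz,1,0,100,0.805,T,1
Cz,2,100,200,2.976,T,1
Cz,3,200,300,0.436,,1
Cz,4,300,400,0.371,,1
Cz,5,400,500,2.356,T,1
Cz,6,500,600,3.061,T,1
Cz,7,600,700,1.074,T,1
T8,1,0,100,1.240,T,1
T8,2,100,200,-0.646,,-1
T8,3,200,300,-0.946,D,1
T8,4,300,400,-0.148,,-1
T8,5,400,500,-1.806,T,-1
T8,6,500,600,-0.749,,-1
T8,7,600,700,0.753,,1
P7,1,0,100,1.366,T,1
P7,2,100,200,-0.106,,-1
P7,3,200,300,-2.172,D,1
P7,4,300,400,-1.772,D,1
P7,5,400,500,2.118,T,1
P7,6,500,600,0.870,T,1
P7,7,600,700,0.822,T,1
Pz,1,0,100,-2.256,T,-1
Pz,2,100,200,0.993,T,1
Pz,3,200,300,2.139,T,1
Pz,4,300,400,-2.181,T,-1
Pz,5,400,500,-3.538,T,-1
Pz,6,500,600,1.241,T,1
Pz,7,600,700,3.268,T,1
P8,1,0,100,-2.720,T,-1
P8,2,100,200,-1.200,T,-1
P8,3,200,300,-0.526,,-1
P8,4,300,400,-0.620,,-1
P8,5,400,500,0.293,,1
P8,6,500,600,2.100,T,1
P8,7,600,700,0.846,T,1
O1,1,0,100,-0.882,T,-1
O1,2,100,200,2.402,T,1
O1,3,200,300,2.020,T,1
O1,4,300,400,0.147,,1
O1,5,400,500,-0.059,,-1
O1,6,500,600,-0.677,,-1
O1,7,600,700,-0.314,,-1
Oz,1,0,100,-0.045,,-1
Oz,2,100,200,0.060,,1
Oz,3,200,300,0.561,,1
Oz,4,300,400,0.388,,1
Oz,5,400,500,-2.287,T,-1
Oz,6,500,600,-2.029,T,-1
Oz,7,600,700,-1.690,T,-1
O2,1,0,100,1.196,T,1
O2,2,100,200,-2.431,T,-1
O2,3,200,300,-1.358,T,-1
O2,4,300,400,1.062,T,1
O2,5,400,500,0.729,,1
O2,6,500,600,-0.742,,-1
O2,7,600,700,-1.466,T,-1
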