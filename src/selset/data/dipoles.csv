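label,x,y,z,mx,my,mz,p,peak_ms,width_ms,condition
precuneus,0.06,-0.6,0.45,0.079745,-0.797452,0.598089,1.0,150,100.0,target
supramarginal_gyrus,-0.55,-0.4,0.3,-0.73994,-0.538138,0.403604,1.0,250,100.0,target
middle_frontal_gyrus,0.38,0.4,0.25,0.62735,0.660368,0.41273,1.0,350,100.0,target
insula,0.38,-0.05,0.08,0.970538,-0.127702,0.204324,1.0,450,100.0,target
thalamus_md,0.08,-0.18,0.1,0.362143,-0.814822,0.452679,1.0,550,100.0,target
caudate_body,0.14,0.05,0.15,0.662919,0.236757,0.710271,1.0,650,100.0,target
middle_temporal_gyrus,0.45,-0.6,0.05,0.598671,-0.798228,0.066519,1.0,250,100.0,distractor
claustrum,-0.3,0.05,0.05,-0.973329,0.162221,0.162221,1.0,550,100.0,distractor
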