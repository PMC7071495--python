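label,range_mm,source,condition
precuneus,2,child,target
supramarginal_gyrus,3,child,target
middle_frontal_gyrus,1,child,target
insula,4,child,target
thalamus_md,3,child,target
caudate_body,2,child,target
middle_temporal_gyrus,3,child,distractor
claustrum,4,child,distractor
precuneus,2,simulated,target
supramarginal_gyrus,2,simulated,target
middle_frontal_gyrus,3,simulated,target
insula,3,simulated,target
thalamus_md,4,simulated,target
caudate_body,1,simulated,target
middle_temporal_gyrus,4,simulated,distractor
claustrum,3,simulated,distractor
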