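indicator_id,label,p_min,p_max,l_min,l_max
a1,Psychological and awareness training for medical staff,1,3,4,5
a2,Training on epidemic prevention skills for medical staff,1,3,2,4
a3,Work rights and responsibilities during the epidemic,2,3,1,3
a4,Hospital emergency medical supplies,2,4,3,4
a5,Hospital emergency fund preparation,2,4,4,4
a6,Hospital emergency personnel preparation,2,4,3,4
a7,Management of public service facilities in hospitals,1,3,3,4
a8,Hospital public health management,2,3,2,4
a9,Early warning supervision and management of hospitals,2,4,2,3
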