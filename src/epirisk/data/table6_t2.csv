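indicator_id,label,p_min,p_max,l_min,l_max
a1,Psychological and awareness training for medical staff,3,4,4,5
a2,Training on epidemic prevention skills for medical staff,4,5,2,4
a3,Work rights and responsibilities during the epidemic,3,4,1,3
a4,Hospital emergency medical supplies,5,5,3,4
a5,Hospital emergency fund preparation,5,5,4,4
a6,Hospital emergency personnel preparation,5,5,3,4
a7,Management of public service facilities in hospitals,5,5,3,4
a8,Hospital public health management,4,4,2,4
a9,Early warning supervision and management of hospitals,3,4,2,3
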