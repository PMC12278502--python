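Salt,AnionSizeScore,ChargeDelocalizationScore,CoordinatingAbilityScore
LiI,1.0,1.0,9.0
LiBF4,1.15,3.0,6.0
LiClO4,1.3,4.0,5.5
LiOTf,1.9,5.0,5.0
LiNTf2,3.4,7.0,3.0
LiPF6,3.6,8.0,2.5
LiB(C6F5)4,9.5,10.0,0.5
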