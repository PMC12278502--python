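Exp,Conf,LiSalt,LiSaltEq,Acid,AcceptorEq,ConcM,PartEt2O,PartMeCN,MS,TempC,YieldPct,BetaPct,Batch,Objective,Mode,PrintedHVContrPct,PrintedHVContrAlphaPct
56,alpha,LiPF6,4.1,Formic,2.5,0.03,0.01,0.27,None,25,74,33,11,beta,,24,50
57,alpha,LiB(C6F5)4,2.6,Oxalic,1.4,0.1,0.26,0.22,5A,25,0,0,11,beta,,0,0
58,beta,LiClO4,2.9,Oxalic,2.3,0.28,0.06,0.06,3A,25,99,57,11,alpha,,56,43
59,beta,LiI,4.5,Formic,1.4,0.08,0.31,0.31,4A,0,75,15,11,alpha,,11,64
60,beta,LiNTf2,4.8,Oxalic,1.6,0.05,0.09,0.47,3A,25,101,79,11,alpha,,80,21
61,alpha,LiNTf2,1,TFA,2,0.17,0.22,0.31,4A,0,53,84,12,beta,,44,8
62,alpha,LiClO4,3.6,TFA,0.9,0.06,0.73,0.2,None,0,53,40,12,beta,,21,32
63,alpha,LiB(C6F5)4,1.6,Oxalic,1.1,0.23,0.48,0.19,4A,25,0,0,12,alpha,,0,0
64,alpha,LiOTf,3.9,TFA,1.9,0.3,0.24,0.66,3A,25,80,66,12,alpha,,53,27
65,beta,LiOTf,4,None,2,0.2,0.44,0.15,4A,0,48,46,12,alpha,,22,26
66,alpha,LiPF6,4.5,Acetic,2.1,0.13,0.58,0.1,4A,25,85,73,13,beta,,63,23
67,beta,LiPF6,3,Acetic,2.7,0.18,0.59,0.2,3A,0,98,67,13,beta,,65,32
68,beta,LiI,1.8,Formic,1,0.18,0.3,0.12,4A,25,76,7,13,alpha,,6,71
69,beta,LiOTf,4.3,Oxalic,1.1,0.05,0.01,0.59,5A,25,12,68,13,alpha,,8,4
70,alpha,LiPF6,2.2,TFA,1.5,0.11,0.35,0.14,4A,25,74,79,13,alpha,,58,16
71,alpha,LiPF6,3.2,Oxalic,1.9,0.06,0.05,0.63,4A,25,96,82,14,beta,,78,17
72,beta,LiBF4,4.6,Formic,2.7,0.28,0.33,0.11,3A,0,99,60,14,beta,,60,17
73,alpha,LiPF6,1.3,Formic,2.4,0.23,0.36,0.63,None,25,80,65,14,alpha,,52,40
74,alpha,LiClO4,4.1,Oxalic,1.1,0.17,0.24,0.66,5A,25,29,64,14,alpha,,18,10
75,beta,LiPF6,5,Acetic,1.5,0.3,0.44,0.15,3A,0,97,63,14,alpha,,62,36
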