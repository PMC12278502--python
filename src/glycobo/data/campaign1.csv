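Exp,Conf,LiSalt,LiSaltEq,Acid,AcceptorEq,ConcM,PartEt2O,PartMeCN,MS,TempC,YieldPct,BetaPct,Batch,Objective,Mode,PrintedHVContrPct
1,alpha,LiPF6,3.4,Oxalic,1.7,0.18,0.51,0.05,3A,25,87,69,1,beta,random,60
2,beta,LiI,1.5,Acetic,1.3,0.3,0.29,0.06,4A,25,96,13,1,beta,random,12
3,beta,LiI,3.5,TFA,2.8,0.26,0.51,0.08,3A,0,69,11,1,beta,random,8
4,alpha,LiI,1.6,None,1.9,0.27,0.11,0.41,3A,25,13,36,1,beta,random,5
5,alpha,LiClO4,1.7,Acetic,1.4,0.25,0.11,0.81,3A,0,64,78,1,beta,random,50
6,beta,LiNTf2,2.2,Oxalic,1.7,0.19,0.41,0.08,3A,0,61,63,1,beta,random,38
7,beta,LiClO4,1.7,None,1.8,0.18,0.19,0.11,None,0,59,48,1,beta,random,28
8,beta,LiClO4,3,Acetic,2.2,0.25,0.56,0.16,4A,25,74,47,1,beta,random,35
9,alpha,LiBF4,2.6,Oxalic,3,0.22,0.75,0.18,4A,25,69,73,1,beta,random,51
10,alpha,LiB(C6F5)4,1,Acetic,2.1,0.24,0.65,0.28,5A,25,10,0,1,beta,random,0
11,alpha,LiPF6,2.8,Oxalic,1.5,0.17,0.33,0.04,None,25,97,18,2,beta,,18
12,beta,LiOTf,1.5,Formic,3,0.09,0.44,0.15,None,25,81,49,2,beta,,40
13,beta,LiNTf2,3.2,Formic,0.8,0.11,0.15,0.6,4A,0,28,86,2,beta,,24
14,alpha,LiOTf,4.6,Oxalic,1.9,0.13,0.05,0.9,4A,25,97,64,2,beta,,62
15,beta,LiPF6,4.1,Acetic,2.2,0.12,0.8,0.12,3A,25,98,65,2,beta,,64
16,alpha,LiNTf2,4.8,TFA,1.2,0.12,0.69,0.28,4A,0,84,78,3,beta,,66
17,alpha,LiPF6,5,Oxalic,2.5,0.03,0.09,0.87,5A,25,93,81,3,beta,,75
18,alpha,LiClO4,5,Formic,1.2,0.28,0.86,0.12,3A,25,71,52,3,beta,,37
19,alpha,LiBF4,4.1,Acetic,2.4,0.1,0.98,0.01,5A,0,58,59,3,beta,,34
20,alpha,LiNTf2,1.8,None,2.8,0.07,0.31,0.15,3A,0,51,86,3,beta,,44
21,alpha,LiBF4,0.5,Formic,1.1,0.18,0.17,0.53,3A,25,82,80,4,beta,,66
22,alpha,LiBF4,2.1,Formic,2.3,0.06,0.82,0.04,3A,0,62,64,4,beta,,40
23,beta,LiOTf,4,TFA,2.5,0.21,0.38,0.49,5A,0,76,65,4,beta,,49
24,alpha,LiPF6,4.2,Acetic,2.6,0.15,0.05,0.44,None,0,92,72,4,beta,,66
25,alpha,LiOTf,3.1,Formic,1.7,0.05,0.13,0.23,5A,25,74,61,4,beta,,45
26,beta,LiB(C6F5)4,2.5,TFA,1.3,0.08,0.1,0.7,5A,25,0,0,5,beta,,0
27,beta,LiOTf,3.3,Oxalic,1,0.07,0.52,0.12,4A,25,81,49,5,beta,,40
28,beta,LiB(C6F5)4,1.5,Formic,2.4,0.16,0.55,0.34,4A,0,0,0,5,beta,,0
29,beta,LiBF4,4.5,Oxalic,1.4,0.26,0.55,0.38,3A,25,94,71,5,beta,,67
30,alpha,LiClO4,3.7,Oxalic,2.3,0.23,0.12,0.56,3A,25,87,79,5,beta,,69
31,beta,LiClO4,3.2,Oxalic,2.5,0.13,0.63,0.34,None,25,99,45,6,beta,,45
32,beta,LiNTf2,4.2,Oxalic,2.7,0.28,0.46,0.25,4A,25,13,77,6,beta,,10
33,beta,LiNTf2,1.2,Oxalic,2.9,0.21,0.04,0.5,4A,0,94,80,6,beta,,75
34,alpha,LiB(C6F5)4,3,TFA,1,0.19,0.03,0.15,4A,25,12,0,6,beta,,0
35,beta,LiPF6,4.1,Formic,2.1,0.05,0.57,0.39,5A,25,57,78,6,beta,,45
36,alpha,LiOTf,3.6,Acetic,2.5,0.17,0.28,0.27,3A,0,95,66,7,beta,,62
37,beta,LiPF6,3.1,Acetic,1.8,0.09,0.4,0.55,4A,0,98,77,7,beta,,76
38,beta,LiClO4,2.5,None,1.3,0.14,0.43,0.49,3A,25,3,0,7,beta,,0
39,alpha,LiBF4,2.5,Oxalic,2.2,0.14,0.29,0.63,4A,0,73,80,7,beta,,59
40,alpha,LiB(C6F5)4,1.5,Formic,2.1,0.24,0.87,0.06,4A,0,33,69,7,beta,,23
41,alpha,LiClO4,0.8,Acetic,2.5,0.27,0.13,0.71,4A,25,58,73,8,beta,,42
42,alpha,LiBF4,2.2,Acetic,1,0.27,0.54,0.29,5A,0,68,74,8,beta,,50
43,alpha,LiOTf,1.8,Acetic,1.9,0.16,0.09,0.47,4A,0,30,73,8,beta,,22
44,beta,LiB(C6F5)4,1.3,None,2.9,0.24,0.21,0.62,5A,0,26,41,8,beta,,11
45,beta,LiClO4,1.8,Oxalic,1.7,0.31,0.7,0.27,4A,25,85,50,8,beta,,42
46,beta,LiPF6,2.7,Formic,2.5,0.2,0.13,0.48,None,25,99,41,9,beta,,41
47,alpha,LiBF4,0.8,TFA,1.4,0.09,0.38,0.06,3A,25,58,74,9,beta,,43
48,alpha,LiBF4,3.5,Acetic,1.4,0.21,0.11,0.73,4A,25,85,77,9,beta,,66
49,beta,LiClO4,5,Formic,1.5,0.18,0.53,0.21,5A,25,100,36,9,beta,,36
50,alpha,LiNTf2,3.2,Formic,1,0.22,0.33,0.31,3A,25,44,81,9,beta,,36
51,alpha,LiPF6,2.7,Acetic,2.3,0.03,0,0.99,5A,0,50,80,10,beta,,40
52,alpha,LiPF6,1.3,Formic,1.2,0.11,0.03,0.11,3A,0,63,80,10,beta,,51
53,beta,LiClO4,0.8,Acetic,2.4,0.1,0.45,0.43,3A,0,56,74,10,beta,,41
54,alpha,LiBF4,3.2,Formic,2.8,0.14,0.57,0.29,3A,0,78,76,10,beta,,59
55,alpha,LiBF4,1.1,TFA,2.5,0.06,0.02,0.36,4A,0,73,80,10,beta,,58
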