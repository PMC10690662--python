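patient,age,sex,mri_findings,mri_status,lobar_localization,pathology,followup_months,engel_class,seeg,surgery,visual,spm,sipcom
1,17,M,R central FLAIR hyperintensity,positive,R Central,FCD 2A,48,1a,MC + LC + MP + LPr R,Idem,MP + LPr + MC + LC R,LPr + LC R,LPr + LC + MP + MC R
2,41,F,R posterior temporal cavernoma + R hippocampal sclerosis,positive,R Temporal,FCD 3A,28,1a,AML + ATL R,Idem,AML + ATL R,N,N
3,41,M,Negative,negative,R Temporal,FCD 3A,4,1a,AML + ATL R,Idem,N,N,N
4,38,M,Bilateral hippocampal sclerosis,positive,R Temporal,Nonspecific gliosis,10,1a,AML + ATL R,Idem,AML + ATL R,AML + ATL R,AML + ATL R
5,33,F,L temporal pole atrophy + L amygdala FLAIR hypersignal,positive,L Temporal,Nonspecific gliosis,2,1a,AML + ATL + OI L,Idem,AML + ATL L,ATL L,AML + ATL L
6,29,M,L temporal pole blurring + L temporal pole atrophy,positive,L Temporal,Nonspecific gliosis,24,1a,AML + ATL L,Idem,AML + ATL L,N,AML + ATL L
7,33,M,Negative,negative,L Temporal,Nonspecific gliosis,32,1a,AML L + ATL L + ATL R,AML + ATL L,AML L,N,N
8,25,M,Negative,negative,R TPO,Normal,35,1a,PLT + LP + TPO R,Idem,AML + ATL + PLT R,N,PLT R
9,24,F,R parieto-occipital scar + R hippocampal sclerosis,positive,R Temporal,NA,13,1a,AML + ATL R,Idem,AML + ATL + PLT R,AML + ATL + PLT R,AML + ATL + PLT R
10,36,F,Negative,negative,R Temporal,NA,3,1a,AML + ATL + PMT + PLT R,Idem,N,ATL + PLT R,ATL + PLT R
11,30,F,Left parietal blurring + L parietal FLAIR signal hyperintensity + L transmantle sign,positive,L Parieto-occipital,NA,4,1a,LP + LO L,Idem,LP + LO L,N,LP + LO L
12,31,F,Negative,negative,R Temporal,FCD 3A,40,1b,ATL R,Idem,ATL R,N,ATL R
13,21,F,L insular FLAIR hypersignal,positive,L Temporal,Normal,12,2b,PLT + ATL + OI L,Idem,AML + ATL + PLT + OI L,N,N
14,40,F,L hippocampal sclerosis,positive,L Temporal,FCD 1C,38,2b,AML + ATL L,Idem,AML + ATL L,N,N
15,50,M,L temporal pole FLAIR hypersignal + L Temporal pole atrophy,positive,L Temporal,FCD 3D,7,3a,AML + ATL L,Idem,AML + ATL L,ATL L,ATL L
16,30,M,Negative,negative,R Frontal,Normal,31,3a,VLPF + DLPF + LPr + MP R,MP + LPr R,N,N,N
17,26,M,R hemispheric atrophy + R amygdala and hippocampus FLAIR hypersignal,positive,R Temporal + TPO,Nonspecific gliosis,17,3a,ATL + PLT + TPO R,Idem,ATL + PLT + OI R,ATL + PLT + OI R,ATL + PLT + OI R
18,26,F,Negative,negative,R Frontal,Nonspecific gliosis,36,3a,VLPF + OI R,Idem,VLPF + OI R,N,VLPF R
19,28,M,Negative,negative,R Central,Nonspecific gliosis,3,4b,MC + LC R,Idem,MC + LC R,N,N
20,34,M,L temporal pole atrophy,positive,L Temporal,Nonspecific gliosis,25,4b,AML + ATL L,Idem,AML + ATL L,N,N
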