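strain,condition,mating_system,overrides,inputs,expected_mating,expected_meiosis,provisional,note
pka1D/cyr1D,nitrogen-rich,homothallic,,pka:0.0,+,+,False,
tor2-51,nitrogen-rich,homothallic,,tor2:0.0,+,+,False,
tor2-51 cgs1D,nitrogen-rich,homothallic,,tor2:0.0;pka:1.5,-,-,False,
tor2-51 pka1D,nitrogen-rich,homothallic,,tor2:0.0;pka:0.0,+,+,False,
nmt1-ste11,nitrogen-rich,homothallic,ks11b:set:0.5,,+,+,False,Ste11 overexpression: strong constitutive synthesis
ste11-T82A,nitrogen-rich,homothallic,,,-,-,False,subsystem ste11 transcription is already constitutive
"ste11-T173A,S218A",nitrogen-rich,homothallic,w_ste11:set:0.3,,-,-,True,mapped as impaired Ste11 function (site kinase unknown)
"ste11-T305D,T317D",nitrogen-rich,homothallic,k_imste11:scale:13.0;k_imphe:set:0.0,,+,+,False,import clamped at the PheS-saturated rate
wild type + LMB,nitrogen-rich,homothallic,k_exste11:set:0.0,,+,+,False,
pat1-114 (30C),nitrogen-rich,homothallic,pat1_t:set:0.5,,+,+,False,
mts2D,nitrogen-rich,homothallic,kd_mei2p:scale:0.1,,+,+,False,
tor2-ts6 mei2D,nitrogen-rich,homothallic,ks_mei2:set:0.0,tor2:0.0,-,-,False,
byr2-DN,nitrogen-rich,homothallic,k_sphe_b:set:0.2;k_iphe:scale:10.0,,-,+,False,"constitutive, hyperactive pheromone signalling"
byr2-DN mei3D,nitrogen-rich,homothallic,k_sphe_b:set:0.2;k_iphe:scale:10.0;k_smei3:set:0.0,,-,+,False,
mei2-8A,nitrogen-rich,homothallic,kp_tor:set:0.0;kp_torp:set:0.0,,+,+,False,
mei2-8A-SATA,nitrogen-rich,homothallic,kp_tor:set:0.0;kp_torp:set:0.0;kp_pat:set:0.0,,-,+,False,
wild type,nitrogen-starved,homothallic,,,+,+,False,
rst2D,nitrogen-starved,homothallic,ks11r:set:0.0,,-,-,False,
cgs1D,nitrogen-starved,homothallic,,pka:1.5,-,-,False,
mei2D,nitrogen-starved,homothallic,ks_mei2:set:0.0,,-,-,False,
mei3D,nitrogen-starved,homothallic,k_smei3:set:0.0,,+,-,False,
mat1pmD,nitrogen-starved,homothallic,k_smat:set:0.0,,-,-,False,
spk1D,nitrogen-starved,homothallic,k_sphe:set:0.0,,-,-,False,
ste11D,nitrogen-starved,homothallic,ks11b:set:0.0;ks11r:set:0.0;ks11a:set:0.0,,-,-,False,
"ste11-T173D,S218D",nitrogen-starved,homothallic,w_ste11:set:0.3,,-,-,True,mapped as impaired Ste11 function (site kinase unknown)
"ste11-T305A,T317A",nitrogen-starved,homothallic,k_imphe:set:0.0,,+,+,False,
ste11-T82D,nitrogen-starved,homothallic,w_ste11:set:0.0,,-,-,False,Cdk1-site mimic: DNA binding abolished
lsk1D,nitrogen-starved,homothallic,w_rpol:set:0.0,,-,-,False,
nmt1-ste11 lsk1D,nitrogen-starved,homothallic,w_rpol:set:0.0;ks11b:set:0.5,,+,+,False,
nmt-tor2,nitrogen-starved,homothallic,k_exnut:scale:2.0,tor2:1.5,-,-,False,Tor2 overexpression: export and Mei2 degradation scaled up
nmt-tor2 cyr1D,nitrogen-starved,homothallic,k_exnut:scale:2.0,tor2:1.5;pka:0.0,+,+,False,
tor2-s65,nitrogen-starved,homothallic,,tor2:1.0,-,-,False,activated Tor2 insensitive to starvation
tor2-s65 pREP41-mei2,nitrogen-starved,homothallic,ks_mei2:scale:10.0,tor2:1.0,+,+,False,
pat1-114 (34C),nitrogen-rich,heterothallic,pat1_t:set:0.001,,-,+,False,
mei2D pat1-114 (34C),nitrogen-rich,heterothallic,pat1_t:set:0.001;ks_mei2:set:0.0,,-,-,False,
nmt-tor2 pat1-114 (34C),nitrogen-rich,heterothallic,pat1_t:set:0.001;k_exnut:scale:2.0,tor2:1.5,-,-,False,
ste11D pat1-114 (34C),nitrogen-rich,heterothallic,pat1_t:set:0.001;ks11b:set:0.0;ks11r:set:0.0;ks11a:set:0.0,,-,-,False,
lsk1D pat1-114 (34C),nitrogen-rich,heterothallic,pat1_t:set:0.001;w_rpol:set:0.0,,-,-,False,
mei2-SATA,nitrogen-rich,heterothallic,kp_pat:set:0.0,,-,+,False,
mei2-L-SATA,nitrogen-rich,heterothallic,kp_pat:set:0.0,,-,+,True,mapped identically to mei2-SATA
mei2-L-SATA lsk1D,nitrogen-rich,heterothallic,kp_pat:set:0.0;w_rpol:set:0.0,,-,-,False,
pat1D mei2D nmt1-mei2,nitrogen-rich,heterothallic,pat1_t:set:0.0;eps_mei2:set:1.0,,-,+,True,constitutive mei2 expression from the nmt1 promoter
mei2D nmt1-mei2,nitrogen-rich,heterothallic,eps_mei2:set:1.0,,-,-,False,
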