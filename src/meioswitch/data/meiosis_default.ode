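par eps_mei2=0.01
par h_mat=4.0
par h_mei2=3.0
par h_mei2h=2.0
par h_mei3=6.0
par h_phe=4.0
par h_pka=4.0
par h_rpol=2.0
par hs=4.0
par k_as=1.0
par k_di=0.0001
par k_exnut=2.0
par k_expat=8.0
par k_exste11=0.1
par k_imphe=6.0
par k_imste11=0.25
par k_iphe=2.0
par k_mmat=2.5
par k_mmei2=0.06
par k_mmei2h=8.0
par k_mmei3=2.0
par k_mphe=0.8
par k_mpka=0.66
par k_mrpol=0.06
par k_mste11=0.12
par k_smat=0.05
par k_smei3=0.018
par k_sphe=0.2
par k_sphe_b=0.0
par k_tapat=2.0
par kd_cplx=0.0001
par kd_mat=0.02
par kd_mei2=0.05
par kd_mei2p=0.2
par kd_mei3=0.05
par kd_phe=0.1
par kd_ste11=0.1
par kdp_mei2=3.0
par km_dp=0.05
par km_p=0.05
par kp_pat=40.0
par kp_tor=0.5
par kp_torp=10.0
par ks11a=0.4
par ks11b=0.002
par ks11r=2.0
par ks_mei2=0.1
par ks_mei2h=0.05
par pat1_t=1.0
par rpol_b=0.05
par w_rpol=1.0
par w_ste11=1.0
done
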