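par a_sk_arrest=0.0
par b55_t=1.0
par eps_b55=0.1
par eps_mei2=0.01
par h_cdk_ste11=4.0
par h_mat=4.0
par h_mei2=3.0
par h_mei2h=2.0
par h_mei3=6.0
par h_phe=4.0
par h_pka=4.0
par h_rpol=2.0
par h_sk_arrest=4.0
par h_slp1=8.0
par hs=4.0
par j_a25=0.01
par j_a_slp1=0.001
par j_a_tf=0.01
par j_awee=0.01
par j_i25=0.01
par j_i_slp1=0.001
par j_i_tf=0.01
par j_iwee=0.01
par j_slp1=0.65
par j_ste9a=0.01
par j_ste9i=0.01
par k25_hi=5.0
par k25_lo=0.05
par k_as=1.0
par k_cdk_ste11=0.3
par k_di=0.0001
par k_exnut=2.0
par k_expat=8.0
par k_exste11=0.1
par k_ib55=0.1
par k_igo=0.1
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
par k_rum1_phes=4.0
par k_sk_arrest=5.0
par k_sk_phes=0.0
par k_smat=0.05
par k_smei3=0.018
par k_sphe=0.2
par k_sphe_b=0.0
par k_tapat=2.0
par ka_iep=0.1
par ka_slp1=1.0
par ka_ste9=1.0
par ka_ste9_slp1=10.0
par ka_tf_m=1.5
par kd_cdc13_b=0.03
par kd_cdc13_slp1=0.1
par kd_cdc13_ste9=1.0
par kd_cplx=0.0001
par kd_mat=0.02
par kd_mei2=0.05
par kd_mei2p=0.2
par kd_mei3=0.05
par kd_phe=0.1
par kd_pool=0.004
par kd_rum1_b=0.01
par kd_rum1_mpf=3.0
par kd_rum1_sk=1.0
par kd_sk=0.1
par kd_slp1=0.1
par kd_ste11=0.1
par kdiss=0.001
par kdp_igo=0.2
par kdp_mei2=3.0
par ki_iep=0.04
par ki_slp1=0.25
par ki_ste9_mpf=35.0
par ki_ste9_sk=2.0
par ki_tf_b=1.0
par ki_tf_mpf=2.0
par km_dp=0.05
par km_p=0.05
par kp_pat=40.0
par kp_tor=0.5
par kp_torp=10.0
par ks11a=0.4
par ks11b=0.002
par ks11r=2.0
par ks_cdc13=0.03
par ks_mei2=0.1
par ks_mei2h=0.05
par ks_rum1=0.1
par ks_sk=0.1
par ks_slp1_b=0.005
par ks_slp1_mpf=0.3
par kwee_hi=1.3
par kwee_lo=0.15
par mpf_exit=0.1
par mpf_mitotic=0.4
par mu=0.00433
par n_pool0=1.8
par pat1_t=1.0
par rpol_b=0.05
par v_a25=1.0
par v_awee=0.25
par v_i25=0.25
par v_iwee=1.0
par w_rpol=1.0
par w_slp1_b55=0.55
par w_ste11=1.0
done
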