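# published dog retrocopy catalogue counts used by the paper-arithmetic report mode
key	value
total_retrocopies	3025
intact	507
pseudogene	2518
parental_genes	1227
parents_with_single_retrocopy	760
chimeric	31
chimeric_recent	9
recent_window_myr	22.5
ks_burst_low	0.02
ks_burst_high	0.06
intact_omega_lt_05	285
intact_omega_mid	160
intact_omega_gt_12	25
intact_omega_denominator	470
pseudo_omega_lt_05	984
pseudo_omega_mid	1419
pseudo_omega_gt_12	106
pseudo_omega_denominator	2509
est_supported_intact	165
est_intact_total	507
est_supported_pseudo	126
est_pseudo_total	2518
movement_inter	2902
movement_intra	77
movement_scaffold_mt	46
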