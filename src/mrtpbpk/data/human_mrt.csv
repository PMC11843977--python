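# Human male-reproductive-organ physiology, mirrored cell-for-cell
# from the study's cross-species table. Flows L/min, volumes L.
# Values are ingested as printed; the validator flags anatomical anomalies.
organ,field,value,unit
testis,plasma_flow,6.90e-1,L/min
testis,blood_cell_flow,5.64e-1,L/min
testis,vascular_volume,0.00345,L
testis,endosomal_volume,0.000575,L
testis,interstitial_volume,0.00661,L
testis,epithelial_volume,0.092,L
testis,luminal_volume,0.00661,L
testis,rete_testis_volume,0.00575,L
epididymis,plasma_flow,3.32e-1,L/min
epididymis,blood_cell_flow,2.71e-1,L/min
epididymis,vascular_volume,0.00537,L
epididymis,endosomal_volume,0.000895,L
epididymis,interstitial_volume,0.01432,L
epididymis,epithelial_volume,0.132,L
epididymis,luminal_volume,0.02506,L
vas_deferens,plasma_flow,3.32e-1,L/min
vas_deferens,blood_cell_flow,2.71e-1,L/min
vas_deferens,vascular_volume,0.0001689,L
vas_deferens,endosomal_volume,2.815e-5,L
vas_deferens,interstitial_volume,0.001689,L
vas_deferens,epithelial_volume,0.0009908,L
vas_deferens,muscular_volume,0.000563,L
vas_deferens,luminal_volume,0.00219,L
seminal_vesicle,plasma_flow,7.39e-1,L/min
seminal_vesicle,blood_cell_flow,8.19e-1,L/min
seminal_vesicle,vascular_volume,0.000213,L
seminal_vesicle,endosomal_volume,0.0000353,L
seminal_vesicle,interstitial_volume,0.000497,L
seminal_vesicle,epithelial_volume,0.00439,L
seminal_vesicle,muscular_volume,0.00071,L
seminal_vesicle,luminal_volume,0.0012496,L
prostate_gland,plasma_flow,1.00,L/min
prostate_gland,blood_cell_flow,6.05e-1,L/min
prostate_gland,vascular_volume,0.001584,L
prostate_gland,endosomal_volume,0.000264,L
prostate_gland,interstitial_volume,0.003696,L
prostate_gland,epithelial_volume,0.03268,L
prostate_gland,muscular_volume,0.00528,L
prostate_gland,luminal_volume,0.00929,L
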