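# Monkey male-reproductive-organ physiology, mirrored cell-for-cell
# from the study's cross-species table. Flows L/min, volumes L.
# Values are ingested as printed; the validator flags anatomical anomalies.
organ,field,value,unit
testis,plasma_flow,1.41e-1,L/min
testis,blood_cell_flow,1.16e-1,L/min
testis,vascular_volume,2.46e-5,L
testis,endosomal_volume,1.23e-7,L
testis,interstitial_volume,5.41e-6,L
testis,epithelial_volume,1.59e-5,L
testis,luminal_volume,1.23e-6,L
testis,rete_testis_volume,1.23e-6,L
epididymis,plasma_flow,5.34e-2,L/min
epididymis,blood_cell_flow,4.37e-2,L/min
epididymis,vascular_volume,8.55e-5,L
epididymis,endosomal_volume,1.43e-5,L
epididymis,interstitial_volume,7.92e-4,L
epididymis,epithelial_volume,1.14e-3,L
epididymis,luminal_volume,8.17e-4,L
vas_deferens,plasma_flow,5.34e-2,L/min
vas_deferens,blood_cell_flow,4.37e-2,L/min
vas_deferens,vascular_volume,2.67e-5,L
vas_deferens,endosomal_volume,4.44e-6,L
vas_deferens,interstitial_volume,6.67e-5,L
vas_deferens,epithelial_volume,4.95e-4,L
vas_deferens,muscular_volume,3.36e-5,L
vas_deferens,luminal_volume,8.67e-5,L
seminal_vesicle,plasma_flow,1.61e-1,L/min
seminal_vesicle,blood_cell_flow,1.32e-1,L/min
seminal_vesicle,vascular_volume,0.00409,L
seminal_vesicle,endosomal_volume,2.045e-5,L
seminal_vesicle,interstitial_volume,8.589e-5,L
seminal_vesicle,epithelial_volume,0.0007198,L
seminal_vesicle,muscular_volume,0.000409,L
seminal_vesicle,luminal_volume,0.002531,L
prostate_gland,plasma_flow,3.79e-1,L/min
prostate_gland,blood_cell_flow,3.10e-1,L/min
prostate_gland,vascular_volume,6.09e-6,L
prostate_gland,endosomal_volume,1.02e-5,L
prostate_gland,interstitial_volume,6.09e-4,L
prostate_gland,epithelial_volume,9.64e-4,L
prostate_gland,muscular_volume,1.02e-4,L
prostate_gland,luminal_volume,2.84e-4,L
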