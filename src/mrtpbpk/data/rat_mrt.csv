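# Rat male-reproductive-organ physiology, mirrored cell-for-cell
# from the study's cross-species table. Flows L/min, volumes L.
# Values are ingested as printed; the validator flags anatomical anomalies.
organ,field,value,unit
testis,plasma_flow,4.28e-3,L/min
testis,blood_cell_flow,3.50e-3,L/min
testis,vascular_volume,4.80e-5,L
testis,endosomal_volume,8.00e-6,L
testis,interstitial_volume,2.24e-5,L
testis,epithelial_volume,1.18e-3,L
testis,luminal_volume,1.56e-4,L
testis,rete_testis_volume,8.00e-5,L
epididymis,plasma_flow,1.21e-2,L/min
epididymis,blood_cell_flow,9.90e-3,L/min
epididymis,vascular_volume,1.10e-5,L
epididymis,endosomal_volume,1.83e-6,L
epididymis,interstitial_volume,2.93e-5,L
epididymis,epithelial_volume,2.69e-4,L
epididymis,luminal_volume,5.22e-5,L
vas_deferens,plasma_flow,6.81e-3,L/min
vas_deferens,blood_cell_flow,5.57e-3,L/min
vas_deferens,vascular_volume,8.91e-7,L
vas_deferens,endosomal_volume,1.49e-6,L
vas_deferens,interstitial_volume,2.22e-6,L
vas_deferens,epithelial_volume,1.51e-5,L
vas_deferens,muscular_volume,1.80e-6,L
vas_deferens,luminal_volume,4.30e-6,L
seminal_vesicle,plasma_flow,1.31e-2,L/min
seminal_vesicle,blood_cell_flow,1.08e-2,L/min
seminal_vesicle,vascular_volume,6.87e-6,L
seminal_vesicle,endosomal_volume,1.15e-6,L
seminal_vesicle,interstitial_volume,1.60e-5,L
seminal_vesicle,epithelial_volume,4.03e-5,L
seminal_vesicle,muscular_volume,2.29e-5,L
seminal_vesicle,luminal_volume,1.42e-4,L
prostate_gland,plasma_flow,2.01e-2,L/min
prostate_gland,blood_cell_flow,1.65e-2,L/min
prostate_gland,vascular_volume,6.87e-6,L
prostate_gland,endosomal_volume,1.15e-6,L
prostate_gland,interstitial_volume,1.60e-5,L
prostate_gland,epithelial_volume,4.03e-5,L
prostate_gland,muscular_volume,2.29e-5,L
prostate_gland,luminal_volume,1.42e-4,L
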