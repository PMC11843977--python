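# Mouse male-reproductive-organ physiology, mirrored cell-for-cell from the
# study's literature-compiled table. The printed 'Blood Flow' column is
# ingested as blood-cell flow and 'Plasma Flow' as plasma flow (the ratio is
# exactly 0.45/0.55, i.e. hematocrit 0.45). Flows L/min, volumes L.
organ,field,value,unit
testis,blood_cell_flow,0.00081,L/min
testis,plasma_flow,0.00099,L/min
testis,vascular_volume,7.07e-6,L
testis,endosomal_volume,1.18e-6,L
testis,interstitial_volume,1.89e-5,L
testis,epithelial_volume,1.74e-4,L
testis,luminal_volume,3.48e-5,L
testis,rete_testis_volume,1.56e-6,L
epididymis,blood_cell_flow,0.003078,L/min
epididymis,plasma_flow,0.003762,L/min
epididymis,vascular_volume,4.35e-6,L
epididymis,endosomal_volume,7.20e-7,L
epididymis,interstitial_volume,1.16e-5,L
epididymis,epithelial_volume,1.07e-4,L
epididymis,luminal_volume,2.14e-5,L
vas_deferens,blood_cell_flow,0.001179,L/min
vas_deferens,plasma_flow,0.001441,L/min
vas_deferens,vascular_volume,3.9e-7,L
vas_deferens,endosomal_volume,2.00e-8,L
vas_deferens,interstitial_volume,2.20e-7,L
vas_deferens,epithelial_volume,2.55e-6,L
vas_deferens,muscular_volume,2.45e-7,L
vas_deferens,luminal_volume,7.84e-7,L
seminal_vesicle,blood_cell_flow,0.002142,L/min
seminal_vesicle,plasma_flow,0.002618,L/min
seminal_vesicle,vascular_volume,4.1234e-7,L
seminal_vesicle,endosomal_volume,1.033e-7,L
seminal_vesicle,interstitial_volume,1.44e-6,L
seminal_vesicle,epithelial_volume,3.637e-6,L
seminal_vesicle,muscular_volume,2.061e-6,L
seminal_vesicle,luminal_volume,1.3e-5,L
prostate_gland,blood_cell_flow,0.000006921,L/min
prostate_gland,plasma_flow,0.000008459,L/min
prostate_gland,vascular_volume,4.758e-7,L
prostate_gland,endosomal_volume,1.19e-7,L
prostate_gland,interstitial_volume,5.47e-6,L
prostate_gland,epithelial_volume,9.52e-6,L
prostate_gland,muscular_volume,6.26178e-6,L
prostate_gland,luminal_volume,1.94e-6,L
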