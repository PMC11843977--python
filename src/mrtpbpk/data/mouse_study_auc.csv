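# Literature-reported mouse AUC(0-168h) values (h*nmol/L) for a 10 mg/kg IV
# antibody dose: model-predicted and observed (non-compartmental) exposure per
# tissue. Used as the worked-example input for %PE and ABC calculations.
tissue,auc_predicted,auc_observed
plasma,87505,70799
testis,1495,1355
epididymis,2253,1988
seminal_vesicle,369,355
vas_deferens,1757,1783
prostate_gland,423,436
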