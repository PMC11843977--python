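# Male-reproductive-tract parameters estimated for the mouse model
# (final literature-reported estimates; standard errors in comments).
clup_btb: 6.78e-2          # L/h/L, blood-testis-barrier pinocytosis   (SE 4.30e-6)
clup_e_testis: 1.27e2      # L/h/L, testis endothelial pinocytosis     (SE 4.10e-5)
q_retetestis: 1.20e-8      # L/h, rete testis luminal flow             (SE 3.40e-8, CV% 283)
q_ep: 1.60e-4              # L/h, epididymis luminal flow              (SE 1.10e-4)
q_vd: 2.00e-5              # L/h, vas deferens luminal flow            (SE 1.90e-6)
q_sv: 9.40e-5              # L/h, seminal vesicle luminal flow         (SE 1.20e-5)
q_pg: 1.60e-5              # L/h, prostate gland luminal flow          (SE 8.60e-7)
beb_volume_epididymis: 2.80e-4  # L, blood-epididymal-barrier volume   (SE 4.00e-5)
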