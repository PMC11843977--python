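# Global antibody / FcRn kinetic parameters shared by all organs.
# FcRn in the blood-testis barrier is ten-fold lower than in vascular
# endothelium (4.98e-6 M vs 4.98e-5 M). The remaining values are
# platform-model-style defaults for an IgG in an hFcRn mouse, chosen once for
# realistic plasma kinetics; every entry is overridable from user config.
clup: 0.55               # pinocytosis uptake clearance, L/h per L endosomal volume
kon_fcrn: 8.06e7         # FcRn association rate, 1/(M*h)
koff_fcrn: 6.55          # FcRn dissociation rate, 1/h
kdeg: 42.9               # degradation of unbound endosomal antibody, 1/h
fr: 0.715                # recycling fraction of FcRn-bound antibody
fcrn_endothelium: 4.98e-5  # free FcRn concentration in endothelial endosomes, M
fcrn_btb: 4.98e-6          # free FcRn at the blood-testis barrier, M
sigma_vascular: 0.95     # vascular reflection coefficient (default)
sigma_vascular_overrides:
  brain: 0.99
sigma_lymph: 0.2         # interstitial (lymphatic) reflection coefficient
sigma_epithelial: 0.95   # paracellular interstitial->lumen reflection (MRT organs)
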