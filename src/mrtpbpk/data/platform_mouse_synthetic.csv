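# SYNTHETIC stand-in platform physiology for a 0.028 kg mouse (non-reproductive
# organs). The published platform-model tables are not redistributable here, so
# this file is constructed from standard rodent physiology conventions: 5%
# vascular volume (hematocrit 0.45), endosomal volume 0.5% of organ volume,
# literature-typical interstitial fractions and plasma flows. Fully overridable.
# Lung plasma flow is derived at load time from circulatory mass-balance closure.
# Flows L/h, volumes L.
organ,field,value,unit
lung,vascular_volume,5.5e-06,L
lung,blood_cell_volume,4.5e-06,L
lung,endosomal_volume,1e-06,L
lung,interstitial_volume,3.8e-05,L
heart,plasma_flow,0.0366,L/h
heart,blood_cell_flow,0.0299455,L/h
heart,vascular_volume,4.18e-06,L
heart,blood_cell_volume,3.42e-06,L
heart,endosomal_volume,7.6e-07,L
heart,interstitial_volume,2.432e-05,L
kidney,plasma_flow,0.0803,L/h
kidney,blood_cell_flow,0.0657,L/h
kidney,vascular_volume,1.2925e-05,L
kidney,blood_cell_volume,1.0575e-05,L
kidney,endosomal_volume,2.35e-06,L
kidney,interstitial_volume,9.4e-05,L
muscle,plasma_flow,0.0591,L/h
muscle,blood_cell_flow,0.0483545,L/h
muscle,vascular_volume,0.00031075,L
muscle,blood_cell_volume,0.00025425,L
muscle,endosomal_volume,5.65e-05,L
muscle,interstitial_volume,0.001469,L
skin,plasma_flow,0.0331,L/h
skin,blood_cell_flow,0.0270818,L/h
skin,vascular_volume,0.0001375,L
skin,blood_cell_volume,0.0001125,L
skin,endosomal_volume,2.5e-05,L
skin,interstitial_volume,0.0015,L
brain,plasma_flow,0.0119,L/h
brain,blood_cell_flow,0.00973636,L/h
brain,vascular_volume,1.32e-05,L
brain,blood_cell_volume,1.08e-05,L
brain,endosomal_volume,2.4e-06,L
brain,interstitial_volume,8.64e-05,L
adipose,plasma_flow,0.0135,L/h
adipose,blood_cell_flow,0.0110455,L/h
adipose,vascular_volume,5.445e-05,L
adipose,blood_cell_volume,4.455e-05,L
adipose,endosomal_volume,9.9e-06,L
adipose,interstitial_volume,0.0002673,L
thymus,plasma_flow,0.00105,L/h
thymus,blood_cell_flow,0.000859091,L/h
thymus,vascular_volume,8.25e-07,L
thymus,blood_cell_volume,6.75e-07,L
thymus,endosomal_volume,1.5e-07,L
thymus,interstitial_volume,4.5e-06,L
liver,plasma_flow,0.0109,L/h
liver,blood_cell_flow,0.00891818,L/h
liver,vascular_volume,4.2625e-05,L
liver,blood_cell_volume,3.4875e-05,L
liver,endosomal_volume,7.75e-06,L
liver,interstitial_volume,0.00031,L
spleen,plasma_flow,0.00568,L/h
spleen,blood_cell_flow,0.00464727,L/h
spleen,vascular_volume,2.75e-06,L
spleen,blood_cell_volume,2.25e-06,L
spleen,endosomal_volume,5e-07,L
spleen,interstitial_volume,2.5e-05,L
pancreas,plasma_flow,0.00563,L/h
pancreas,blood_cell_flow,0.00460636,L/h
pancreas,vascular_volume,2.75e-06,L
pancreas,blood_cell_volume,2.25e-06,L
pancreas,endosomal_volume,5e-07,L
pancreas,interstitial_volume,1.7e-05,L
small_intestine,plasma_flow,0.0358,L/h
small_intestine,blood_cell_flow,0.0292909,L/h
small_intestine,vascular_volume,2.0075e-05,L
small_intestine,blood_cell_volume,1.6425e-05,L
small_intestine,endosomal_volume,3.65e-06,L
small_intestine,interstitial_volume,0.0001387,L
large_intestine,plasma_flow,0.0105,L/h
large_intestine,blood_cell_flow,0.00859091,L/h
large_intestine,vascular_volume,1.155e-05,L
large_intestine,blood_cell_volume,9.45e-06,L
large_intestine,endosomal_volume,2.1e-06,L
large_intestine,interstitial_volume,7.98e-05,L
bone,plasma_flow,0.0152,L/h
bone,blood_cell_flow,0.0124364,L/h
bone,vascular_volume,7.7e-05,L
bone,blood_cell_volume,6.3e-05,L
bone,endosomal_volume,1.4e-05,L
bone,interstitial_volume,0.00028,L
other,plasma_flow,0.0123,L/h
other,blood_cell_flow,0.0100636,L/h
other,vascular_volume,4.125e-05,L
other,blood_cell_volume,3.375e-05,L
other,endosomal_volume,7.5e-06,L
other,interstitial_volume,0.000225,L
plasma,pool_volume,9.44e-4,L
blood_cell,pool_volume,7.73e-4,L
lymph_node,pool_volume,1.13e-4,L
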