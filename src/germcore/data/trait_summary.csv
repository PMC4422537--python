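descriptor,mean_whole,mean_core,mean_mini,var_whole,var_core,var_mini,equality_wc_cc,equality_wc_mc,equality_cc_mc,n_classes,homogeneity_wc_cc,homogeneity_wc_mc,homogeneity_cc_mc,shannon_whole,shannon_core,shannon_mini
V040,4.5,4.5,4.5,0.24,0.23,0.21,0.57,0.71,0.94,11,0.97,0.87,0.76,0.87,0.88,0.83
V050,1.7,1.7,1.6,0.05,0.05,0.04,0.97,0.48,0.52,10,0.96,0.54,0.68,0.88,0.87,0.8
V120,22.2,22.1,22.6,36.89,38.93,44.45,0.56,0.38,0.27,15,0.8,0.01,0.85,0.79,0.69,0.63
V130,40.5,40.6,44.2,149.75,150.39,142.2,0.73,0,0,14,0.88,0,0,0.9,0.89,0.79
V400,44.2,44.2,44.9,14.49,15.05,14.06,0.91,0,0,11,0.68,0.06,0.05,0.89,0.86,0.8
V510,7.3,7.3,7.3,1.01,1.01,0.76,0.63,0.89,0.92,11,0.95,0.6,0.34,0.74,0.69,0.71
V700,11.0,11.0,11.0,1.59,1.64,1.83,0.88,0.28,0.28,13,0.97,0.06,0.12,0.78,0.77,0.75
V770,37.5,37.6,36.9,87.24,85.42,87.19,0.61,0.09,0.07,14,0.68,0.22,0.12,0.68,0.7,0.61
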