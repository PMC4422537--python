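locus,alleles_core,alleles_mini,genotypes_core,genotypes_mini,shannon_core,shannon_mini,nei_core,nei_mini
AVRDC-MB41,5,5,9,8,1.013,1.108,0.608,0.651
AVRDC-MB44,4,4,7,7,0.913,1.059,0.54,0.636
AVRDC-MB46,6,6,10,10,0.474,0.752,0.266,0.434
AVRDC-MB59,7,7,12,10,0.762,0.856,0.504,0.508
AVRDC-MB60,3,3,4,4,0.681,0.704,0.48,0.502
AVRDC-MB65,4,4,10,10,1.284,1.287,0.707,0.706
AVRDC-MB99,5,5,10,10,0.721,0.837,0.456,0.499
AVRDC-MB148,3,3,4,4,0.694,0.713,0.497,0.503
AVRDC-MB159,5,5,8,8,0.601,0.802,0.354,0.459
AVRDC-MB162,11,10,36,31,1.503,1.74,0.694,0.768
AVRDC-MB180,13,13,24,24,0.796,1.315,0.355,0.585
AVRDC-MB197,8,8,17,16,0.987,1.297,0.496,0.657
AVRDC-MB204,7,7,17,11,1.126,1.185,0.647,0.661
AVRDC-MB241,5,5,8,8,0.342,0.695,0.145,0.34
AVRDC-MB314,8,6,12,10,0.986,1.123,0.582,0.649
AVRDC-MB340,9,7,15,11,0.747,0.92,0.46,0.542
AVRDC-MB347,5,4,9,6,1.209,1.225,0.667,0.68
DMB-SSR80,3,3,5,5,0.595,0.694,0.398,0.472
DMB-SSR125,4,4,8,8,0.691,0.912,0.381,0.503
DMB-SSR130,7,7,14,13,0.904,1.185,0.473,0.604
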