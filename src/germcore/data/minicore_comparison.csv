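locus,alleles_core,alleles_optimizer,alleles_region,alleles_random,genotypes_core,genotypes_optimizer,genotypes_region,genotypes_random
AVRDC-MB41,5,5,3,4,9,8,6,7
AVRDC-MB44,4,4,3,3,7,7,6,6
AVRDC-MB46,6,6,4,6,10,10,5,7
AVRDC-MB59,7,7,6,6,12,10,7,7
AVRDC-MB60,3,3,3,3,4,4,4,4
AVRDC-MB65,4,4,4,4,10,10,10,10
AVRDC-MB99,5,5,4,5,10,10,5,8
AVRDC-MB148,3,3,2,2,4,4,3,3
AVRDC-MB159,5,5,4,5,8,8,7,6
AVRDC-MB162,11,10,8,9,36,31,23,28
AVRDC-MB180,13,13,7,12,24,24,14,19
AVRDC-MB197,8,8,7,6,17,16,14,12
AVRDC-MB204,7,7,4,6,17,11,8,9
AVRDC-MB241,5,5,4,5,8,8,6,7
AVRDC-MB314,8,6,6,4,12,10,9,7
AVRDC-MB340,9,7,5,6,15,11,8,9
AVRDC-MB347,5,4,4,4,9,6,6,6
DMB-SSR80,3,3,2,3,5,5,3,5
DMB-SSR125,4,4,4,4,8,8,7,7
DMB-SSR130,7,7,5,7,14,13,9,13
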