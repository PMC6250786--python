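# C. briggsae genome specification: chromosome,length,kind
# Lengths are approximate assembly sizes in bp; only relative marker placement
# matters for the statistics, and this file is user-overridable.
chromosome,length,kind
I,15455979,autosome
II,16627154,autosome
III,14578851,autosome
IV,17485439,autosome
V,19495157,autosome
X,21540570,sex_chromosome
MT,14420,mitochondrial
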