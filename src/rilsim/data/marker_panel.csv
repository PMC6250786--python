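# Default genotyping panel: nine AFLP indel markers on four of the five
# autosomes and the X (none on chromosome I), one mitochondrial RFLP (cb18178)
# and one X-linked RFLP (cb51757 at 12.0 Mbp).
# Anchored placements: cb-m205 -> III (middle), cb-m124 and cb-m127 -> X,
# cb51757 -> X:12,000,000, cb18178 -> MT. All other positions are editable
# placeholders; cb-m197 is the third X marker but is unanchored (its identity
# among the remaining AFLP names is not established).
name,chromosome,position,assay
cb-m26,II,8000000,AFLP
cb-m56,III,4000000,AFLP
cb-m205,III,7300000,AFLP
cb-m161,IV,6000000,AFLP
cb-m172,IV,12000000,AFLP
cb-m103,V,9700000,AFLP
cb-m197,X,5000000,AFLP
cb-m124,X,9000000,AFLP
cb-m127,X,16000000,AFLP
cb18178,MT,7000,RFLP
cb51757,X,12000000,RFLP
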