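# Curated mouse cell-cycle gene symbols (proliferation / cell-cycle program)
# used by the cluster-level cell-cycle screen.  Newline-delimited; lines
# starting with '#' are ignored.
Mki67
Stmn1
Top2a
Ccnb1
Ccnb2
Ccna2
Ccne1
Ccne2
Ccnd1
Cdk1
Cdk2
Cdk4
Cdk6
Cdc20
Cdc25c
Cdc6
Bub1
Bub1b
Plk1
Aurka
Aurkb
Birc5
Mcm2
Mcm3
Mcm4
Mcm5
Mcm6
Mcm7
Pcna
Rrm1
Rrm2
Tyms
Fen1
Mad2l1
Ndc80
Cenpa
Cenpe
Cenpf
Ube2c
Tpx2
Kif11
Kif23
Prc1
Anln
Cks1b
Cks2
Gins2
Hells
E2f1
Cdt1
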