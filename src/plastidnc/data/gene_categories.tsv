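# Default chloroplast gene -> functional category map (editable).
# Categories: photosynthesis, gene_expression, misc_protein, ycf, tRNA, rRNA.
# tRNA/rRNA genes are resolved by feature kind and need no entry here.
psbA	photosynthesis
psbB	photosynthesis
psbC	photosynthesis
psbD	photosynthesis
psbE	photosynthesis
psbF	photosynthesis
psbH	photosynthesis
psbI	photosynthesis
psbJ	photosynthesis
psbK	photosynthesis
psbL	photosynthesis
psbM	photosynthesis
psbN	photosynthesis
psbT	photosynthesis
psbZ	photosynthesis
ycf9	photosynthesis
psaA	photosynthesis
psaB	photosynthesis
psaC	photosynthesis
psaI	photosynthesis
psaJ	photosynthesis
petA	photosynthesis
petB	photosynthesis
petD	photosynthesis
petG	photosynthesis
petL	photosynthesis
petN	photosynthesis
ndhA	photosynthesis
ndhB	photosynthesis
ndhC	photosynthesis
ndhD	photosynthesis
ndhE	photosynthesis
ndhF	photosynthesis
ndhG	photosynthesis
ndhH	photosynthesis
ndhI	photosynthesis
ndhJ	photosynthesis
ndhK	photosynthesis
rbcL	photosynthesis
atpA	photosynthesis
atpB	photosynthesis
atpE	photosynthesis
atpF	photosynthesis
atpH	photosynthesis
atpI	photosynthesis
rpoA	gene_expression
rpoB	gene_expression
rpoC1	gene_expression
rpoC2	gene_expression
rps2	gene_expression
rps3	gene_expression
rps4	gene_expression
rps7	gene_expression
rps8	gene_expression
rps11	gene_expression
rps12	gene_expression
rps14	gene_expression
rps15	gene_expression
rps16	gene_expression
rps18	gene_expression
rps19	gene_expression
rpl2	gene_expression
rpl14	gene_expression
rpl16	gene_expression
rpl20	gene_expression
rpl22	gene_expression
rpl23	gene_expression
rpl32	gene_expression
rpl33	gene_expression
rpl36	gene_expression
infA	gene_expression
matK	gene_expression
accD	misc_protein
ccsA	misc_protein
cemA	misc_protein
clpP	misc_protein
orf31	misc_protein
ycf10	misc_protein
ycf1	ycf
ycf1.1	ycf
ycf1.2	ycf
ycf2	ycf
ycf2.1	ycf
ycf3	ycf
ycf4	ycf
ycf5	ycf
ycf6	ycf
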