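gene_label	essential	note
nifB	true	FeMo cofactor biosynthesis
fdxN	false	ferredoxin
nifS	true	cysteine desulfurase
nifU	true	Fe-S scaffold
nifH	true	nitrogenase reductase
nifD	true	nitrogenase alpha subunit
nifK	true	nitrogenase beta subunit
nifE	true	FeMo cofactor scaffold
nifN	true	FeMo cofactor scaffold
nifX	false	FeMo cofactor carrier
nifW	false	nitrogenase stabilization
hesA	false	MoaD-like sulfur carrier
hesB	false	Fe-S assembly
fdxH	false	heterocyte ferredoxin
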