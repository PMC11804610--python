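gene_label	essential	note
hgdA	true	HG exporter component
hgdC	true	ABC transporter component
hgdB	true	ABC transporter component
hglT	true	glycosyltransferase attaching the sugar headgroup
hglE_A	true	ketoacyl synthase (longest island gene)
hglF	true	PKS component
hglG	true	PKS component
hglD	true	PKS component
hglC	true	PKS component
hglA	true	PKS component
hglB	true	thioester reductase
all5343	true	conserved island member
all5342	false	island member
alr5348	false	island member
asr5349	false	island member
asr5350	false	island member
hetN	false	ketoreductase, heterocyte pattern regulator
hetI	false	phosphopantetheinyltransferase
orf19	false	placeholder: 19th island member, label pending authoritative source annotation
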