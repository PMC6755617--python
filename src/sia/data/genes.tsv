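# Synthetic demonstration gene vocabulary (term <TAB> concept id).
BRCA1	SIA:G0001
BRCA2	SIA:G0002
TP53	SIA:G0003
EGFR	SIA:G0004
KRAS	SIA:G0005
BRAF	SIA:G0006
PTEN	SIA:G0007
MYC	SIA:G0008
CDKN2A	SIA:G0009
VEGFA	SIA:G0010
APOE	SIA:G0011
TNF	SIA:G0012
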