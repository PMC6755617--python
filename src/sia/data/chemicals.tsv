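# Synthetic demonstration chemical vocabulary (term <TAB> concept id).
aspirin	SIA:C0001
imatinib	SIA:C0002
tamoxifen	SIA:C0003
doxorubicin	SIA:C0004
cisplatin	SIA:C0005
paclitaxel	SIA:C0006
metformin	SIA:C0007
dexamethasone	SIA:C0008
caffeine	SIA:C0009
ibuprofen	SIA:C0010
gefitinib	SIA:C0011
rapamycin	SIA:C0012
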