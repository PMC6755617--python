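# Synthetic demonstration disease vocabulary (term <TAB> concept id).
# A small stand-in for a full UMLS-derived disease term list.
breast cancer	SIA:D0001
cancer	SIA:D0002
lung cancer	SIA:D0003
colorectal cancer	SIA:D0004
melanoma	SIA:D0005
glioblastoma	SIA:D0006
leukemia	SIA:D0007
lymphoma	SIA:D0008
type 2 diabetes mellitus	SIA:D0009
diabetes	SIA:D0010
asthma	SIA:D0011
alzheimer disease	SIA:D0012
parkinson disease	SIA:D0013
rheumatoid arthritis	SIA:D0014
hypertension	SIA:D0015
cystic fibrosis	SIA:D0016
multiple sclerosis	SIA:D0017
hepatitis	SIA:D0018
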