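# Synthetic demonstration organism vocabulary (term <TAB> concept id).
Escherichia coli	SIA:O0001
Homo sapiens	SIA:O0002
Mus musculus	SIA:O0003
Drosophila melanogaster	SIA:O0004
Saccharomyces cerevisiae	SIA:O0005
Danio rerio	SIA:O0006
Caenorhabditis elegans	SIA:O0007
Arabidopsis thaliana	SIA:O0008
zebrafish	SIA:O0009
Rattus norvegicus	SIA:O0010
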