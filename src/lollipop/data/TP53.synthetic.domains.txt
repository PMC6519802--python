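# protein-record v1
# Synthetic stand-in record for human TP53 (offline demo/test fixture).
# Domain names follow the Pfam-style annotation of the p53 protein;
# spans are plausible residue ranges, not a verbatim UniProt export.
accession	P04637
gene_symbol	TP53
organism_id	9606
length	393
retrieved_at	fixture
domain	P53_TAD	6	29
domain	P53	95	288
domain	P53_tetramer	318	358
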