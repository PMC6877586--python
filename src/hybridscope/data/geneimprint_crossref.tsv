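gene	origin_in_hybrid	reported_allele	reported_species
AMPD3	paternal	maternal	Mus musculus
ATP10A	paternal	maternal	Homo sapiens, Mus musculus and Macaca mulatta
B4GALNT4	maternal	maternal	Homo sapiens
CDKN1C	paternal	maternal	Homo sapiens and Mus musculus
EGFL7	paternal	paternal	Homo sapiens (predicted)
GLIS3	maternal	paternal	Homo sapiens
GPT	paternal	maternal	Homo sapiens
GRB10	maternal	maternal	Ovis aries
HSPA6	paternal	maternal	Homo sapiens (predicted)
IGF2	paternal	paternal	Ovis aries, Homo sapiens and Mus musculus
KCNQ1	paternal	maternal	Homo sapiens and Mus musculus
PON1	paternal	maternal	Homo sapiens
PRIM2	paternal	biallelic_or_conflicting	Homo sapiens
TH	paternal	maternal	Mus musculus
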