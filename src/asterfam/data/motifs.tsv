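element	consensus	functional_class
ABRE	ACGTG	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
as-1	TGACGTCA	hormone
ERE	ATTTCAAA	hormone
MYC	CATTTG	stress
MYB	CAACAG	stress
MYB-like	TAACCA	stress
ARE	AAACCA	stress
STRE	AGGGG	stress
AAGAA-motif	GAAAGAA	stress
Box-4	ATTAAT	light
G-box	CACGTG	light
GT1-motif	GGTTAA	light
CAT-box	GCCACT	development
O2-site	GATGAYRTGR	development
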