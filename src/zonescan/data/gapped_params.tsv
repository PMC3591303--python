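# Published gapped Karlin-Altschul parameters per (matrix, gap open, gap extend).
# Columns: matrix	gip	gep	lambda	K
BLOSUM62	11	1	0.267	0.041
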