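; Miniature restriction-enzyme catalogue, GCG flavor.
; Six commercially available enzymes used by the test fixtures:
; name, site length, annotated recognition sequence (' = top-strand cut).
;
AlwI	9	GGATCNNNN'	!
ApeKI	5	G'CWGC	!
AvaII	5	G'GWCC	!
BsiWI	6	C'GTACG	!
SspI	6	AAT'ATT	!
TaqI	4	T'CGA	!
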