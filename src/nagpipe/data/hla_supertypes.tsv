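allele	supertype
HLA-A*01:01	A01
HLA-A*02:01	A02
HLA-A*02:03	A02
HLA-A*02:06	A02
HLA-A*02:07	A02
HLA-A*03:01	A03
HLA-A*11:01	A03
HLA-A*23:01	A24
HLA-A*24:02	A24
HLA-A*25:01	A01
HLA-A*26:01	A01
HLA-A*29:02	A01
HLA-A*30:01	A03
HLA-A*30:02	A01
HLA-A*31:01	A03
HLA-A*32:01	A01
HLA-A*33:01	A03
HLA-A*66:01	A03
HLA-A*68:01	A03
HLA-A*68:02	A02
HLA-A*69:01	A02
HLA-A*74:01	A03
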