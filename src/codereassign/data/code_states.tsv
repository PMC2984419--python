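taxon	code
Streptophyta	STANDARD
Prasinophytes	STANDARD
Trebouxiophyceae	STANDARD
Chlorophyceae	STANDARD
Ulvales_Ulotrichales	STANDARD
Ignatius	STANDARD
Trentepohliales	TAR_GLN
Dasycladales	TAR_GLN
Bryopsidales	STANDARD
Cladophorales	TAR_GLN
Blastophysa	TAR_GLN
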