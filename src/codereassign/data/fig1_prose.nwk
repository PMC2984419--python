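(Streptophyta:0.60,(Prasinophytes:0.50,((Trebouxiophyceae:0.35,Chlorophyceae:0.35):0.08,((Ulvales_Ulotrichales:0.30,Ignatius:0.28):0.05,(Trentepohliales:0.26,((Dasycladales:0.18,Bryopsidales:0.20):0.05,(Cladophorales:0.15,Blastophysa:0.14):0.07):0.04):0.06):0.05):0.07):0.10);
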