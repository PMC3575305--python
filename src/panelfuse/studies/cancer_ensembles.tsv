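classifier	Ensemble A	Ensemble B	Ensemble C	Ensemble D	Ensemble E	Ensemble F
mRNA-Classifier1	X			X	X
mRNA-Classifier2					X
mRNA-Classifier3			X		X
mRNA-Classifier4					X
mRNA-Classifier5					X
mRNA-Classifier6					X
mRNA-Classifier7						X
mRNA-Classifier8						X
mRNA-Classifier9						X
mRNA-Classifier10				X		X
mRNA-Classifier11			X			X
mRNA-Classifier12		X		X		X
miRNA-Classifier1	X				X
miRNA-Classifier2			X		X
miRNA-Classifier3				X	X
miRNA-Classifier4				X	X
miRNA-Classifier5					X
miRNA-Classifier6					X
miRNA-Classifier7						X
miRNA-Classifier8						X
miRNA-Classifier9						X
miRNA-Classifier10						X
miRNA-Classifier11				X		X
miRNA-Classifier12		X	X			X
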