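classifier	Ensemble 1	Ensemble 2	Ensemble 3	Ensemble 4	Ensemble 5
Genomics 1	X	X	X		X
Genomics 2		X			X
Genomics 3			X	X	X
Genomics 4		X			X
Genomics 5				X	X
Proteomics 1	X	X	X		X
Proteomics 2			X		X
Proteomics 3				X	X
Proteomics 4		X			X
Proteomics 5			X		X
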