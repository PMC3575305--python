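classifier	platform	method	features	sensitivity	specificity	auc
Genomics 1	genomic	LDA	24	0.73	0.90	0.73
Genomics 2	genomic	SVM	50	0.82	0.95	0.96
Genomics 3	genomic	RF	50	0.64	0.95	0.92
Genomics 4	genomic	EN	43	0.73	1.00	0.93
Genomics 5	genomic	EN	174	0.73	1.00	0.95
Proteomics 1	proteomic	SVM	12	0.64	0.95	0.94
Proteomics 2	proteomic	EN	10	0.64	0.81	0.90
Proteomics 3	proteomic	SVM	33	0.55	0.81	0.83
Proteomics 4	proteomic	EN	13	0.55	0.86	0.85
Proteomics 5	proteomic	SVM	13	0.64	0.95	0.94
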