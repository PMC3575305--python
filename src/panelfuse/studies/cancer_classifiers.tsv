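classifier	platform	method	features	accuracy	sensitivity	specificity	auc
mRNA-Classifier1	mrna	EN	182	0.9298	0.9737	0.8421	0.9737
mRNA-Classifier2	mrna	EN	73	0.9123	1.0000	0.7368	0.9709
mRNA-Classifier3	mrna	EN	36	0.8947	0.9737	0.7368	0.9501
mRNA-Classifier4	mrna	LDA	2	0.9298	0.9211	0.9474	0.9640
mRNA-Classifier5	mrna	RF	500	0.8947	0.9737	0.7368	0.9418
mRNA-Classifier6	mrna	SVM	500	0.9298	0.9474	0.8947	0.9640
mRNA-Classifier7	mrna	EN	43	0.9123	0.9474	0.8421	0.9598
mRNA-Classifier8	mrna	EN	25	0.9298	0.9737	0.8421	0.9612
mRNA-Classifier9	mrna	EN	17	0.9298	0.9737	0.8421	0.9695
mRNA-Classifier10	mrna	LDA	2	0.9298	0.9211	0.9474	0.9640
mRNA-Classifier11	mrna	RF	50	0.9298	0.9474	0.8947	0.9584
mRNA-Classifier12	mrna	SVM	50	0.8947	0.9211	0.8421	0.9557
miRNA-Classifier1	mirna	EN	66	0.8947	0.9211	0.8421	0.9626
miRNA-Classifier2	mirna	EN	21	0.9474	0.9737	0.8947	0.9709
miRNA-Classifier3	mirna	EN	8	0.9649	0.9737	0.9474	0.9723
miRNA-Classifier4	mirna	LDA	4	0.9298	0.9211	0.9474	0.9626
miRNA-Classifier5	mirna	RF	152	0.8947	0.8947	0.8947	0.9765
miRNA-Classifier6	mirna	SVM	152	0.9123	0.9474	0.8421	0.9626
miRNA-Classifier7	mirna	EN	36	0.9298	0.9474	0.8947	0.9709
miRNA-Classifier8	mirna	EN	16	0.9298	0.9474	0.8947	0.9848
miRNA-Classifier9	mirna	EN	12	0.9474	0.9737	0.8947	0.9806
miRNA-Classifier10	mirna	LDA	4	0.9298	0.9211	0.9474	0.9626
miRNA-Classifier11	mirna	RF	50	0.9123	0.9211	0.8947	0.9778
miRNA-Classifier12	mirna	SVM	50	0.8947	0.9211	0.8421	0.9612
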