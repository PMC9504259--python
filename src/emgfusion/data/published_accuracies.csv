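dataset,method,accuracy
angeles,EmgPCA-L2,67.20
angeles,EmgLDA-L2,74.70
angeles,EmgCNN,85.80
angeles,EmgLSTM,84.65
angeles,BpRssLdaMlp,79.50
angeles,IdfMahal,93.50
angeles,EmgEnsembleNet-P,92.80
angeles,EmgEnsembleNet-M,95.55
cu,EmgPCA-L2,42.69
cu,EmgLDA-L2,42.97
cu,EmgCNN,62.22
cu,EmgLSTM,58.25
cu,BpRssLdaMlp,54.75
cu,IdfMahal,54.81
cu,EmgEnsembleNet-P,69.75
cu,EmgEnsembleNet-M,75.86
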