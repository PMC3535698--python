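tool	tpr	fpr	tnr	fnr
TargetScan	0.4082	0.0877	0.9123	0.5918
miRanda	0.3371	0.0783	0.9217	0.6629
PicTar	0.1798	0.0390	0.9610	0.8202
mirTarget	0.2285	0.0302	0.9698	0.7715
PITA	0.7603	0.3942	0.6058	0.2397
Diana-microT	0.4045	0.1474	0.8526	0.5955
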