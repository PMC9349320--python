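locus	chrom	start	end
IGH	14	106032614	107288051
IGK	2	89156874	90274235
IGL	22	22380474	23265085
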