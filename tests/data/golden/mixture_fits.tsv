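animal	gene_id	n_tissues	k	alphas	weights	phi	loglik	lrt_trail
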