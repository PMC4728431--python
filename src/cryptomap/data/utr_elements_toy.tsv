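motif	class
ATTTA	destabilizing
TATTTAT	destabilizing
TTATTTATT	destabilizing
GTTTG	stabilizing
CCGCCC	stabilizing
TGTGTGT	stabilizing
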