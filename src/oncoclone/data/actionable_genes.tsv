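#gene	event	note
PIK3CA	mutation	PI3K pathway inhibitors
ALK	mutation	ALK tyrosine-kinase inhibitors
ALK	amplification	ALK tyrosine-kinase inhibitors
MYC	amplification	BET-bromodomain / aurora-kinase inhibition
MCL1	amplification	MCL1/BH3-mimetic inhibitors
IGF1R	amplification	IGF1R inhibitors
CCND2	amplification	CDK4/6 inhibitors
CCND3	amplification	CDK4/6 inhibitors
CDK6	amplification	CDK4/6 inhibitors
NFKBIA	deletion	NF-kB pathway modulation
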