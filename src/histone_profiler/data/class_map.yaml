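# Default mapping from BLAST subject ids / HMM domain names to candidate
# classes. Users extend this for their own query sets.
H2A_HUMAN: H2A
H2B_HUMAN: H2B
H3_HUMAN: H3
H4_HUMAN: H4
H1_HUMAN: H1
Linker_histone: H1
DVNP: DVNP
DVNP_SYNTH: DVNP
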