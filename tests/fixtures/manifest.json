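{
 "aipw_oracle_6rec.csv": "9692b7b159854a5dc1c5426af7ab919c1ccede50d1ef716fa2697a10d80deb5d",
 "demo_simple1_n300.csv": "7d6aee5af6b6d5d316b6ae1df8e9f69d6a9aed9622ffb4d92efc9001ddfee005",
 "linear_noiseless.csv": "ccced2d670e0b53876c816c11299a61c94d4e716b135c07fe3f7c74914fec970"
}
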