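>TUA_NTERM_K40 species=synthetic family=TUA span=1-60 terminal_met=0
MSECINIHIGQAGVQIGNACWELYCLEHGIQPDGRMPSDKTVGGGDDSFNTRAVFVDLEP
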