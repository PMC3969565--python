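(Eco,((Ngr,Tbr),(Ath,(Ddi,(Sce,(Tad,(Nve,(Dme,(Cin,(Dre,Hsa))))))))));
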