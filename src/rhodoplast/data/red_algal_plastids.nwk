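((Cyanidium,Cyanidioschyzon),(Porphyridium,((Porphyra,Pyropia),(Calliarthron,((Chondrus,Cruoria),(Gracilaria,Grateloupia))))));
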