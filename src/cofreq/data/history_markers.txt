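# Section markers opening a (patient) history section.
history
past medical history
medical history
surgical history
past surgical history
pmh
psh
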