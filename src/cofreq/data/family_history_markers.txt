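# Section markers opening a family-history section.
family history
family medical history
fh
fhx
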