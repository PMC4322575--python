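# Post-mention negation triggers: the mention is negated when one of these
# phrases starts within the token window after it.
was ruled out
were ruled out
is ruled out
are ruled out
has been ruled out
have been ruled out
was not seen
is unlikely
unlikely
was excluded
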