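# Pre-mention negation triggers: the mention is negated when one of these
# phrases ends within the token window before it.
no
not
without
denies
denied
deny
negative for
no evidence of
no sign of
no signs of
absence of
free of
rules out
ruled out
cannot see
never developed
never had
fails to reveal
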