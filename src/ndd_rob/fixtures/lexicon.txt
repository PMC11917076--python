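# Synonym lexicon for overlap screening: one pair per line, comma-separated.
# Stemming is applied on load; transitive closure is deliberately NOT taken.
hyperactive, overactive
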