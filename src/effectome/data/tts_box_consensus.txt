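# Default tts-box motif (IUPAC consensus + allowed mismatches).
# This is an approximate conserved core of the rhizobial TtsI binding site,
# shipped for convenience; analyses of real genomes should replace it with
# the consensus or PWM from the primary literature on tts-boxes.
TCGTCARCTTTTCG
max_mismatch=2
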