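patient,applied,software,experienced,intermediate,unexperienced
1,56,24,22,24,22
2,71,56,46,29,26
3,52,22,20,22,20
4,73,43,34,27,44
5,56,28,26,17,22
6,79,53,31,27,27
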