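# Ramachandran four-class region grid (glycine)
# rows: phi from -180 to 170 step 10; columns: psi from -180 to 170 step 10
# F=most favored, A=additionally allowed, G=generously allowed, D=disallowed
A A G G G G G A A A A A A A A A A A A A A G G G A A A A A A A A A A A A
F A G G G G G A A A A A A A A A A A A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A A A A A A A A A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
F A G G G G G A A A A F F F F F F F A A A G G G A A A A F F F F F F F F
A A G G G G G A A A A F F F F F F F A A A G G G A A A A A A A A A A A A
A A G G G G G A A A A A A A A A A A A A A G G G A A A A A A A A A A A A
A A G G G G G A A A A A A A A A A A A A A G G G A A A A A A A A A A A A
G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G
G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G
G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G
G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G G
A A A A A A A A A A A A G G G A A A A A A A A A A A A A A G G G G G A A
A A A A A A A A A A A A G G G A A A A A A A A A A A A A A G G G G G A A
A A A A A A A A A A A A G G G A A A F F F F F F F A A A A G G G G G A A
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A F F F F F F F A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A A A A A A A A A A A A G G G G G A F
F F F F F F F F A A A A G G G A A A A A A A A A A A A A A G G G G G A F
A A A A A A A A A A A A G G G A A A A A A A A A A A A A A G G G G G A A
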