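name	sequence	role
27F	AGAGTTTGATCCTGGCTCAG	forward
1492R	GGTTACCTTGTTACGACTT	reverse
GS.619F	GGGGTTAAATCCATGTGTGCT	forward
GS.1144R	CAGTTCARTTAGAGTCC	reverse
GSB600F	GGGGGTTAAATCCATGTG	forward
1392R	ACGGGCGGTGTGTAC	reverse
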