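type_label	sequence	expected_spacer_length	length_tolerance
IIIAB	GTTGCAMRRGWKKSWKCCCCGYMAGGGGATKRHYDC	41	10
I-E	GTAGTCCCCACRCRYGTGGGGATGGMCSD	32	10
I-C	GTTGCACCGGCCCGAAAGGGCCGGTGAGGATTGAAAC	38	10
I-B	GTTGCAAACCYCGTYAGCCTCGTAGAGGATTGAAAC	36	10
I-U	GTTGCATCCAAGCTTCACAGCTTGGCTACGTTGCAGG	36	10
I-A	GTTTCAAACCCTYATAGGTACGGTYMRAAG	36	10
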