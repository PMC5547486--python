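# Synthetic default domain coordinates for the human SIAH paralogs and the
# B. floridae SINA reference.  The published analysis took exact coordinates
# from the NCBI protein entries, which are not reprinted anywhere; these
# spans are reconstructed from the printed constraints (SIAH1 core #41-#282,
# SIAH2 core #80-#324, SBS 25 columns, DIMER 48 columns, RING ~36 residues,
# C3HC4/SZF zinc-finger architecture) and should be replaced with database
# coordinates for real-data work.
# name	reference_id	domain	start	end
SIAH1	NP_003022.3	RING	41	76
SIAH1	NP_003022.3	SZF	90	150
SIAH1	NP_003022.3	SBS	151	175
SIAH1	NP_003022.3	DIMER	235	282
SIAH2	NP_005058.3	RING	80	115
SIAH2	NP_005058.3	SZF	129	189
SIAH2	NP_005058.3	SBS	190	214
SIAH2	NP_005058.3	DIMER	277	324
SIAH3	NP_942146.2	S3UNS	1	40
SIAH3	NP_942146.2	SZF	90	150
SIAH3	NP_942146.2	SBS	151	175
SIAH3	NP_942146.2	DIMER	213	260
SINA	XP_002609562.1	RING	41	76
SINA	XP_002609562.1	SZF	90	150
SINA	XP_002609562.1	SBS	151	175
SINA	XP_002609562.1	DIMER	235	282
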