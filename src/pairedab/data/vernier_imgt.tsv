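# Vernier-zone framework positions (Foote & Winter 1992) translated from
# Kabat to IMGT numbering. SYNTHETIC STAND-IN: the translation below was
# produced in-house from conserved anchor residues (Cys 23/104, Trp 41,
# FR4 Trp/Phe 118) with linear interpolation between anchors; positions
# adjacent to CDR loops are approximate because the exact Kabat->IMGT
# correspondence there depends on loop length. Edit freely.
chain_type	imgt_position	kabat_position
H	2	2
H	32	27
H	33	28
H	34	29
H	35	30
H	52	47
H	53	48
H	54	49
H	76	67
H	78	69
H	80	71
H	82	73
H	87	78
H	105	93
H	106	94
H	118	103
L	2	2
L	4	4
L	41	35
L	42	36
L	52	46
L	53	47
L	54	48
L	55	49
L	74	64
L	76	66
L	78	68
L	79	69
L	81	71
L	118	98
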