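ATOM      1  N   GLY A   1       4.500   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   2       5.200   1.100   0.400  1.00  0.00           C
ATOM      3  C   GLY A   3       6.100  -0.800  -0.300  1.00  0.00           C
ATOM      4  O   GLY A   4       3.900   2.000  -1.200  1.00  0.00           O
ATOM      5  CB  GLY A   5       7.400   1.500   0.900  1.00  0.00           C
ATOM      6  SG  CYS A   6       8.200  -1.200   1.600  1.00  0.00           S
HETATM    7  O   HOH A   7       2.000   2.000   2.000  1.00  0.00           O
END
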