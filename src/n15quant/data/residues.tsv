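# Monoisotopic residue (monomer) elemental compositions for the 20 standard
# amino acids, i.e. the free amino acid minus one water.  A peptide of n
# residues is the sum of its residue compositions plus one water.
# columns: symbol	formula
G	C2H3N1O1
A	C3H5N1O1
S	C3H5N1O2
P	C5H7N1O1
V	C5H9N1O1
T	C4H7N1O2
C	C3H5N1O1S1
L	C6H11N1O1
I	C6H11N1O1
N	C4H6N2O2
D	C4H5N1O3
Q	C5H8N2O2
K	C6H12N2O1
E	C5H7N1O3
M	C5H9N1O1S1
H	C6H7N3O1
F	C9H9N1O1
R	C6H12N4O1
Y	C9H9N1O2
W	C11H10N2O1
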