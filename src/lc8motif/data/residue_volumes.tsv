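# Mean residue volumes (Zamyatnin, A^3) and the four-bin assignment used
# by the volume scheme.  The bin ranges are <106, 122-142, 155-171 and
# >200 A^3; residues whose tabulated volume falls between two ranges are
# assigned to the nearest range boundary.
residue	volume	bin
G	60.1	small
A	88.6	small
S	89.0	small
C	108.5	small
D	111.1	small
P	112.7	small
N	114.1	medium
T	116.1	medium
E	138.4	medium
V	140.0	medium
Q	143.8	medium
H	153.2	large
M	162.9	large
I	166.7	large
L	166.7	large
K	168.6	large
R	173.4	large
F	189.9	very_large
Y	193.6	very_large
W	227.8	very_large
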