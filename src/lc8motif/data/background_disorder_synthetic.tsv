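# Residue background frequencies for intrinsically disordered regions.
# SYNTHETIC stand-in table: constructed with the canonical composition
# bias of disordered sequence (disorder-promoting P/E/S/K/Q/G enriched,
# order-promoting W/C/F/Y/I/L/V depleted), normalized to sum to 1.
# It stands in for a frequency table derived from a curated disorder
# database, which cannot be redistributed here.
residue	frequency
A	0.0780
C	0.0090
D	0.0550
E	0.0950
F	0.0250
G	0.0740
H	0.0210
I	0.0340
K	0.0810
L	0.0640
M	0.0180
N	0.0380
P	0.0890
Q	0.0470
R	0.0490
S	0.0930
T	0.0580
V	0.0480
W	0.0050
Y	0.0190
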