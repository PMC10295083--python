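A	0.0825
C	0.0137
D	0.0545
E	0.0675
F	0.0386
G	0.0707
H	0.0227
I	0.0596
K	0.0584
L	0.0966
M	0.0242
N	0.0406
P	0.0470
Q	0.0393
R	0.0553
S	0.0656
T	0.0534
V	0.0687
W	0.0108
Y	0.0292
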