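aa,three,max_asa
A,ALA,129.0
R,ARG,274.0
N,ASN,195.0
D,ASP,193.0
C,CYS,167.0
Q,GLN,225.0
E,GLU,223.0
G,GLY,104.0
H,HIS,224.0
I,ILE,197.0
L,LEU,201.0
K,LYS,236.0
M,MET,224.0
F,PHE,240.0
P,PRO,159.0
S,SER,155.0
T,THR,172.0
W,TRP,285.0
Y,TYR,263.0
V,VAL,174.0
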