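residue,atom_name,category
ASP,OD1,N
ASP,OD2,N
GLU,OE1,N
GLU,OE2,N
*,OXT,N
LYS,NZ,P
ARG,NH1,P
ARG,NH2,P
ARG,NE,P
SER,OG,D
THR,OG1,D
TYR,OH,D
CYS,SG,D
ASN,ND2,D
GLN,NE2,D
TRP,NE1,D
ASN,OD1,Ac
GLN,OE1,Ac
PHE,CG,Ar
PHE,CD1,Ar
PHE,CD2,Ar
PHE,CE1,Ar
PHE,CE2,Ar
PHE,CZ,Ar
TYR,CG,Ar
TYR,CD1,Ar
TYR,CD2,Ar
TYR,CE1,Ar
TYR,CE2,Ar
TYR,CZ,Ar
TRP,CG,Ar
TRP,CD1,Ar
TRP,CD2,Ar
TRP,CE2,Ar
TRP,CE3,Ar
TRP,CZ2,Ar
TRP,CZ3,Ar
TRP,CH2,Ar
HIS,CG,Ar
HIS,CE1,Ar
HIS,CD2,Ar
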