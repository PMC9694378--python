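# Ligand atom typing rules. One rule per line: SMARTS<TAB>category.
# Priority = file order; the first matching rule wins. Categories:
# N (Negative), P (Positive), D (Donor), Ac (Acceptor), Ar (Aromatic),
# H (Hydrophobic), O (Other). Hydrogens inherit their heavy atom's category.
# -- Negative: formal anions and acidic oxygens of carboxylate/phosphate/sulfonate
[*-]	N
[OX1;$([OX1]=[CX3][OX2H1,OX1-])]	N
[OX2H1;$([OX2H1][CX3]=[OX1])]	N
[O;$([OX1,OX2H1][P,S](=O)(=O)),$([OX1]=[P,S])]	N
# -- Positive: formal cations, guanidinium/amidinium, protonatable amines
[*+;!$([*+][O-,S-])]	P
[NX3;$([NX3][CX3](=[NX2,NX3+])[NX3])]	P
[NX2;$([NX2]=[CX3][NX3])]	P
[NX3;H2,H1,H0;$([NX3]([#6,#1])([#6,#1])[#6]);!$([NX3][CX3]=[O,N,S]);!$([NX3]a);!$([NX3][a])]	P
# -- Donor: N/O/S bearing at least one hydrogen
[#7,#8,#16;!H0]	D
# -- Acceptor: N/O with an available lone pair
[OX1,OX2]	Ac
[NX1,NX2]	Ac
[nX2]	Ac
[NX3;!$([NX3]a);$([NX3][#6])]	Ac
# -- Aromatic
[a]	Ar
# -- Hydrophobic: C or S bonded only to C/H/S
[#6;!$([#6]~[!#6;!#1;!#16])]	H
[#16;!$([#16]~[!#6;!#1;!#16])]	H
# -- Fallback
[*]	O
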