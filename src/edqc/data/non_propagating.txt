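# Non-propagating compound codes: mainly metal ions.  Contacts to these
# residues neither reject a ligand nor merge ligand components, and the
# residues themselves are never emitted as ligands.  They still count as
# binding-site members.  One code per line; '#' starts a comment.
NA
K
LI
RB
CS
MG
CA
SR
BA
ZN
MN
MN3
FE
FE2
CU
CU1
NI
CO
CD
HG
AL
PB
AG
AU
PT
YB
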