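# Compound codes never treated as ligands: waters, common crystallization
# solvents, cryoprotectants, buffers and additives.  One code per line;
# lines starting with '#' are comments.  Edit freely or override via the CLI.
HOH
DOD
WAT
SO4
PO4
GOL
EDO
PEG
PG4
PGE
1PE
P6G
2PE
ACT
ACY
DMS
DMF
CL
BR
IOD
NO3
FMT
MPD
MRD
TRS
EPE
MES
CIT
FLC
TLA
TAR
MLI
BME
DTT
SCN
AZI
NH4
CAC
IMD
BCT
CO3
EOH
MOH
IPA
BTB
NHE
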