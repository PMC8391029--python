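# SYNTHETIC placeholder hydrophobicity scale (arbitrary units).
# Small value = hydrophilic, large value = hydrophobic.  Replace this file
# with an empirical scale of your choice for real analyses; tests use
# synthetic scales only.
residue,index
ARG,0.05
LYS,0.10
ASP,0.10
GLU,0.12
ASN,0.25
GLN,0.28
HIS,0.35
SER,0.38
THR,0.42
GLY,0.50
ALA,0.55
CYS,0.58
PRO,0.60
TYR,0.62
MET,0.70
TRP,0.72
VAL,0.80
LEU,0.85
ILE,0.88
PHE,0.90
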