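# Maximum accessible surface area (A^2) of residue X in an extended
# Gly-X-Gly tripeptide, used to normalize absolute ASA into RSA (%).
# Values: Miller, Janin, Lesk & Chothia, J Mol Biol 196 (1987) 641-656,
# as tabulated by Rost & Sander (1994). Overridable with a custom table.
res_name,max_asa
ALA,113.0
ARG,241.0
ASN,158.0
ASP,151.0
CYS,140.0
GLN,189.0
GLU,183.0
GLY,85.0
HIS,194.0
ILE,182.0
LEU,180.0
LYS,211.0
MET,204.0
PHE,218.0
PRO,143.0
SER,122.0
THR,146.0
TRP,259.0
TYR,229.0
VAL,160.0
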