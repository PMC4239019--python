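# 20-gene molecular subgroup classifier panel (members of the published
# 24-gene classifier represented on the U133A array)
LEF1
RUNX2
DCX
MAB21L1
PTCH1
PDLIM3
NEUROG1
DLL3
PDGFA
FOXG1B
GRM1
VAMP4
CDKN1C
SERPINF1
NRL
CRX
NMNAT2
SMARCD3
GABRA5
DCC
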