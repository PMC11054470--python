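# Reconstructed 52-gene VHE DEG list (SYNTHETIC in part).
# 23 symbols are recoverable from the published candidate-ranking gene lists
# of the three strongest signature-reversal drugs, 5 more are published
# no-interaction-data input genes; the remaining 24 are synthetic G####
# placeholders, and all directions are assigned, not published.
gene	direction
AADAC	down
BIRC3	up
C1R	up
C1S	up
DPP4	up
FABP7	down
HAS3	up
KRT17	up
KRT6A	up
LAPTM5	up
LCN2	up
LOR	down
LYZ	up
MT4	down
PARP9	up
S100A8	up
S100A9	up
SERPINA3	up
SERPINB3	up
SERPINB4	up
SNTB1	down
TMEM173	up
TNC	up
C5ORF46	down
CD207	down
HEPHL1	down
PRSS53	down
S100A7A	up
G9001	up
G9002	down
G9003	up
G9004	down
G9005	up
G9006	down
G9007	up
G9008	down
G9009	up
G9010	down
G9011	up
G9012	down
G9013	up
G9014	down
G9015	up
G9016	down
G9017	up
G9018	down
G9019	up
G9020	down
G9021	up
G9022	down
G9023	up
G9024	down
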