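symbol	direction
DDB2	induced
FAS	induced
GADD45A	induced
RPS27L	induced
EDA2R	induced
ACAD11	induced
TRIM22	induced
SPATA18	induced
AEN	induced
FDXR	induced
MDM2	induced
CDKN1A	induced
PTCHD4	induced
ZMAT3	induced
PANK1	induced
ALDH4A1	induced
ESR1	induced
RGCC	induced
GADD45B	induced
PHLDA3	induced
CCNB1	repressed
PLK1	repressed
EED	repressed
CDK1	repressed
EZH2	repressed
CCNB2	repressed
E2F3	repressed
MYBL2	repressed
FOXM1	repressed
E2F2	repressed
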