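gene,eN,eNPB,NNE,N,NPB,NC,PPR,pEpi
MRK-eN-01,1,0,0,0,0,0,0,0
MRK-eN-02,1,0,0,0,0,0,0,0
MRK-eN-03,1,0,0,0,0,0,0,0
MRK-eN-04,1,0,0,0,0,0,0,0
MRK-eN-05,1,0,0,0,0,0,0,0
MRK-eN-06,1,0,0,0,0,0,0,0
MRK-eN-07,1,0,0,0,0,0,0,0
MRK-eN-08,1,0,0,0,0,0,0,0
MRK-eN-09,1,0,0,0,0,0,0,0
MRK-eN-10,1,0,0,0,0,0,0,0
MRK-eN-11,1,0,0,0,0,0,0,0
MRK-eN-12,1,0,0,0,0,0,0,0
MRK-eNPB-01,0,1,0,0,0,0,0,0
MRK-eNPB-02,0,1,0,0,0,0,0,0
MRK-eNPB-03,0,1,0,0,0,0,0,0
MRK-eNPB-04,0,1,0,0,0,0,0,0
MRK-eNPB-05,0,1,0,0,0,0,0,0
MRK-eNPB-06,0,1,0,0,0,0,0,0
MRK-eNPB-07,0,1,0,0,0,0,0,0
MRK-eNPB-08,0,1,0,0,0,0,0,0
MRK-eNPB-09,0,1,0,0,0,0,0,0
MRK-eNPB-10,0,1,0,0,0,0,0,0
MRK-eNPB-11,0,1,0,0,0,0,0,0
MRK-eNPB-12,0,1,0,0,0,0,0,0
MRK-NNE-01,0,0,1,0,0,0,0,0
MRK-NNE-02,0,0,1,0,0,0,0,0
MRK-NNE-03,0,0,1,0,0,0,0,0
MRK-NNE-04,0,0,1,0,0,0,0,0
MRK-NNE-05,0,0,1,0,0,0,0,0
MRK-NNE-06,0,0,1,0,0,0,0,0
MRK-NNE-07,0,0,1,0,0,0,0,0
MRK-NNE-08,0,0,1,0,0,0,0,0
MRK-NNE-09,0,0,1,0,0,0,0,0
MRK-NNE-10,0,0,1,0,0,0,0,0
MRK-NNE-11,0,0,1,0,0,0,0,0
MRK-NNE-12,0,0,1,0,0,0,0,0
MRK-N-01,0,0,0,1,0,0,0,0
MRK-N-02,0,0,0,1,0,0,0,0
MRK-N-03,0,0,0,1,0,0,0,0
MRK-N-04,0,0,0,1,0,0,0,0
MRK-N-05,0,0,0,1,0,0,0,0
MRK-N-06,0,0,0,1,0,0,0,0
MRK-N-07,0,0,0,1,0,0,0,0
MRK-N-08,0,0,0,1,0,0,0,0
MRK-N-09,0,0,0,1,0,0,0,0
MRK-N-10,0,0,0,1,0,0,0,0
MRK-N-11,0,0,0,1,0,0,0,0
MRK-N-12,0,0,0,1,0,0,0,0
MRK-NPB-01,0,0,0,0,1,0,0,0
MRK-NPB-02,0,0,0,0,1,0,0,0
MRK-NPB-03,0,0,0,0,1,0,0,0
MRK-NPB-04,0,0,0,0,1,0,0,0
MRK-NPB-05,0,0,0,0,1,0,0,0
MRK-NPB-06,0,0,0,0,1,0,0,0
MRK-NPB-07,0,0,0,0,1,0,0,0
MRK-NPB-08,0,0,0,0,1,0,0,0
MRK-NPB-09,0,0,0,0,1,0,0,0
MRK-NPB-10,0,0,0,0,1,0,0,0
MRK-NPB-11,0,0,0,0,1,0,0,0
MRK-NPB-12,0,0,0,0,1,0,0,0
MRK-NC-01,0,0,0,0,0,1,0,0
MRK-NC-02,0,0,0,0,0,1,0,0
MRK-NC-03,0,0,0,0,0,1,0,0
MRK-NC-04,0,0,0,0,0,1,0,0
MRK-NC-05,0,0,0,0,0,1,0,0
MRK-NC-06,0,0,0,0,0,1,0,0
MRK-NC-07,0,0,0,0,0,1,0,0
MRK-NC-08,0,0,0,0,0,1,0,0
MRK-NC-09,0,0,0,0,0,1,0,0
MRK-NC-10,0,0,0,0,0,1,0,0
MRK-NC-11,0,0,0,0,0,1,0,0
MRK-NC-12,0,0,0,0,0,1,0,0
MRK-PPR-01,0,0,0,0,0,0,1,0
MRK-PPR-02,0,0,0,0,0,0,1,0
MRK-PPR-03,0,0,0,0,0,0,1,0
MRK-PPR-04,0,0,0,0,0,0,1,0
MRK-PPR-05,0,0,0,0,0,0,1,0
MRK-PPR-06,0,0,0,0,0,0,1,0
MRK-PPR-07,0,0,0,0,0,0,1,0
MRK-PPR-08,0,0,0,0,0,0,1,0
MRK-PPR-09,0,0,0,0,0,0,1,0
MRK-PPR-10,0,0,0,0,0,0,1,0
MRK-PPR-11,0,0,0,0,0,0,1,0
MRK-PPR-12,0,0,0,0,0,0,1,0
MRK-pEpi-01,0,0,0,0,0,0,0,1
MRK-pEpi-02,0,0,0,0,0,0,0,1
MRK-pEpi-03,0,0,0,0,0,0,0,1
MRK-pEpi-04,0,0,0,0,0,0,0,1
MRK-pEpi-05,0,0,0,0,0,0,0,1
MRK-pEpi-06,0,0,0,0,0,0,0,1
MRK-pEpi-07,0,0,0,0,0,0,0,1
MRK-pEpi-08,0,0,0,0,0,0,0,1
MRK-pEpi-09,0,0,0,0,0,0,0,1
MRK-pEpi-10,0,0,0,0,0,0,0,1
MRK-pEpi-11,0,0,0,0,0,0,0,1
MRK-pEpi-12,0,0,0,0,0,0,0,1
MODN-01,1,0,0,1,0,0,0,0
MODN-02,1,0,0,1,0,0,0,0
MODN-03,1,0,0,1,0,0,0,0
MODN-04,1,0,0,1,0,0,0,0
MODN-05,1,0,0,1,0,0,0,0
MODN-06,1,0,0,1,0,0,0,0
MODN-07,1,0,0,1,0,0,0,0
MODN-08,1,0,0,1,0,0,0,0
MODN-09,1,0,0,1,0,0,0,0
MODN-10,1,0,0,1,0,0,0,0
MODN-11,1,0,0,1,0,0,0,0
MODN-12,1,0,0,1,0,0,0,0
MODNC-01,0,1,0,0,1,1,0,0
MODNC-02,0,1,0,0,1,1,0,0
MODNC-03,0,1,0,0,1,1,0,0
MODNC-04,0,1,0,0,1,1,0,0
MODNC-05,0,1,0,0,1,1,0,0
MODNC-06,0,1,0,0,1,1,0,0
MODNC-07,0,1,0,0,1,1,0,0
MODNC-08,0,1,0,0,1,1,0,0
MODNC-09,0,1,0,0,1,1,0,0
MODNC-10,0,1,0,0,1,1,0,0
MODNC-11,0,1,0,0,1,1,0,0
MODNC-12,0,1,0,0,1,1,0,0
MODP-01,0,0,1,0,0,0,1,1
MODP-02,0,0,1,0,0,0,1,1
MODP-03,0,0,1,0,0,0,1,1
MODP-04,0,0,1,0,0,0,1,1
MODP-05,0,0,1,0,0,0,1,1
MODP-06,0,0,1,0,0,0,1,1
MODP-07,0,0,1,0,0,0,1,1
MODP-08,0,0,1,0,0,0,1,1
MODP-09,0,0,1,0,0,0,1,1
MODP-10,0,0,1,0,0,0,1,1
MODP-11,0,0,1,0,0,0,1,1
MODP-12,0,0,1,0,0,0,1,1
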