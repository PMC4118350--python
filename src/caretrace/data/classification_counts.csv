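method,a1,b1,a2,b2,a3,b3,a4,b4,a5,b5
Proposal,386,385,378,373,387,376,379,386,379,382
Bayesian,382,378,369,374,378,379,381,375,376,368
SVM,353,348,357,339,368,359,359,349,356,352
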