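forestland_type,bF,bS,eLa,tA,rP,rS,wP,ewP,wA,yB,eH,rM,rO,sM,wB,Be
bS,0.82,1.0,0,0,0,0.80,0,0,0,0,0.52,0.35,0,0,0.43,0
Bs-eLa-Rs,1.0,0.3,0,0.2,0,0.3,0.34,0,0,0,0.80,0.23,0,0,0.34,0
bF-bS,0.81,1.0,0.10,0,0,0,0.22,0.36,0.36,0,0.4,0.50,0.18,0.72,0.09,0.14
rS-wP-eH,0.80,0,0,0,0.72,1.0,0,0.96,0,0.16,0.52,0,0.08,0.20,0.12,0.24
bF,1.0,0.08,0,0.07,0,0,0.52,0,0,0,0,0.05,0,0,0.67,0
rS-bF-wP,0.50,0,0,0,0,0,0.23,0.14,0.81,1.0,0.74,0.22,0.41,0.77,0.10,0.36
bS-wS,0.07,0.27,0,0,0.14,0,0.02,0,0,1.0,0.9,0,0,0.33,0,0
eH-rS,0.08,0,0,0.13,0.23,0.15,0,0.02,0,0,1.0,0,0.15,0.32,0.02,0.04
bF-rM,0.23,0,0,0,0,0,0.27,0,0.17,1.0,0,0.50,0.47,0,0.46,0.03
tA-wB-rO,0,0,0.67,1.0,0,0,0,0.78,0,0.72,0.11,0.11,0.56,0.94,0.32,0
rM-wB-rO,0.05,0,0.22,0,0,0,0.02,0,0,1.0,0,0.23,0.35,0,0.02,0
sM-Be-yB,0.44,0,0,0,0.68,0,0.20,0.24,0.23,0.75,0.08,0.32,0.32,1.0,0.08,0.54
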