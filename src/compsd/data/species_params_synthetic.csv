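# Synthetic default species-parameter table (16 Acadian-forest species).
# Values are plausible but invented; light-curve columns follow the
# shade-tolerance-class archetypes. Not a transcription of any source.
species_code,shade_tolerance_class,c1,c2,cp,swc_min,psi,swc_max,gdd_min,gdd_max,g_growth,d_max,h_max,age_max,biomass_a,biomass_b,recruit_rate
bF,5,1.0,4.64,0.05,0.10,0.55,0.95,560,2400,120,60,2100,200,0.10,2.40,2.0
bS,4,1.31,3.764,0.0575,0.15,0.65,1.00,450,1900,90,50,1900,250,0.11,2.38,1.5
eH,5,1.0,4.64,0.05,0.10,0.50,0.90,1200,3000,100,120,3100,600,0.09,2.45,1.0
eLa,1,2.24,1.136,0.08,0.20,0.70,1.00,500,2400,150,75,2400,180,0.08,2.35,1.5
wP,3,1.62,2.888,0.065,0.05,0.45,0.85,1100,3200,150,100,3500,450,0.09,2.42,1.2
rP,2,1.93,2.012,0.0725,0.05,0.40,0.80,1100,2100,170,90,3000,350,0.09,2.40,0.8
rS,5,1.0,4.64,0.05,0.10,0.50,0.90,600,1900,85,100,3000,400,0.10,2.42,1.5
wS,3,1.62,2.888,0.065,0.10,0.50,0.90,500,2200,110,90,2800,300,0.10,2.40,1.2
Be,5,1.0,4.64,0.05,0.10,0.50,0.90,1300,3200,110,100,3000,350,0.12,2.45,1.0
rM,3,1.62,2.888,0.065,0.05,0.50,0.95,1300,3500,200,110,3300,150,0.11,2.40,2.5
rO,2,1.93,2.012,0.0725,0.05,0.40,0.85,1500,3800,130,100,3000,300,0.12,2.42,0.8
sM,5,1.0,4.64,0.05,0.10,0.50,0.90,1200,3200,95,110,3350,400,0.12,2.45,1.2
tA,1,2.24,1.136,0.08,0.10,0.55,0.95,600,2500,230,80,3050,120,0.08,2.35,3.0
wA,2,1.93,2.012,0.0725,0.10,0.50,0.90,1400,3500,140,100,3200,260,0.11,2.42,0.8
wB,2,1.93,2.012,0.0725,0.10,0.55,0.95,700,2500,170,70,2600,140,0.10,2.38,2.5
yB,3,1.62,2.888,0.065,0.10,0.55,0.95,900,2600,110,100,3050,300,0.11,2.42,1.5
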