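# Published accuracy assessment of the abiotic-only (original) PSD model
# against 16 species in Nova Scotia forest-inventory plots.  The four count
# columns are in printed order (the header of the source table is ambiguous
# about which middle column is false-positive vs false-negative; agreement
# and kappa are invariant to the choice).  printed_* columns hold the
# values as printed, which for a few rows differ slightly from values
# recomputed from the counts.
species,common_name,plots_no,n_pp,n_pa,n_ap,n_aa,printed_agreement_pct,printed_kappa,printed_class
bF,Balsam fir,281,64,12,62,143,73.6,0.45,moderate
bS,Black spruce,158,14,4,38,102,73.4,0.29,fair
eLa,Eastern larch,76,21,0,36,19,52.6,0.23,fair
tA,Aspen,48,1,0,36,11,25.0,0.01,poor
rP,Red pine,13,1,0,2,10,84.6,0.45,moderate
rS,Red spruce,304,63,42,15,184,81.3,0.56,moderate
wS,White spruce,72,6,2,48,16,30.6,0,poor
wP,White pine,162,42,6,66,48,55.5,0.22,fair
wB,White birch,25,1,1,10,13,56.0,0.02,poor
yB,Yellow birch,53,16,1,21,15,59.5,0.3,fair
eH,Hemlock,47,0,1,1,45,95.5,0.02,poor
rM,Red maple,85,13,4,20,48,71.8,0.34,fair
rO,Red oak,58,0,1,29,28,42.3,0,poor
sM,Sugar maple,27,5,0,4,18,85.2,0.63,good
wA,White ash,136,3,3,48,82,61.4,0.03,poor
Be,Beech,33,8,0,7,18,78.9,0.55,moderate
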