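# Published accuracy assessment of the competition-revised PSD model
# against 16 species in Nova Scotia forest-inventory plots.  Same column
# conventions as assessment_original.csv.
species,common_name,plots_no,n_pp,n_pa,n_ap,n_aa,printed_agreement_pct,printed_kappa,printed_class
bF,Balsam fir,281,64,12,32,204,84.3,0.63,good
bS,Black spruce,158,14,4,22,118,83.5,0.43,moderate
eLa,Eastern larch,76,21,0,10,35,84.9,0.69,good
tA,Aspen,48,1,0,14,33,66.7,0.08,poor
rP,Red pine,13,1,0,2,10,84.6,0.44,moderate
rS,Red spruce,304,63,42,5,194,84.5,0.63,good
wS,White spruce,72,6,2,20,46,70.3,0.23,fair
wP,White pine,162,42,6,46,88,71.4,0.42,moderate
wB,White birch,25,1,1,5,19,76.9,0.16,poor
yB,Yellow birch,53,16,1,5,31,88.7,0.75,very good
eH,Hemlock,47,0,1,1,45,95.7,0.02,poor
rM,Red maple,85,13,4,16,52,76.5,0.42,moderate
rO,Red oak,58,0,1,9,48,82.8,0,poor
sM,Sugar maple,27,5,0,2,20,92.6,0.78,very good
wA,White ash,136,3,3,35,94,72.4,0.08,poor
Be,Beech,33,8,0,3,22,90.9,0.78,very good
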