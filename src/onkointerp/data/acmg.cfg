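# ACMG classifier thresholds (Richards et al. 2015 guideline defaults).
# Allele-frequency cutoffs are fractions in [0, 1].
#   pm2_af : below this (or absent from population data) the variant counts
#            as absent/extremely rare (PM2)
#   bs1_af : above this the frequency is greater than expected for disorder (BS1)
#   ba1_af : above this the variant is common (stand-alone benign, BA1)
pm2_af 0.0001
bs1_af 0.01
ba1_af 0.05

# Fraction of available in-silico predictors that must agree for the
# computational-consensus criteria PP3 (deleterious) / BP4 (benign).
consensus_fraction 0.75

# Per-predictor score cutoffs (scores are in [0, 1]).
# <name>_deleterious : score >= cutoff counts as predicting deleterious
# <name>_benign      : score <= cutoff counts as predicting benign
revel_like_deleterious 0.70
revel_like_benign 0.30
am_like_deleterious 0.56
am_like_benign 0.34
primateai_like_deleterious 0.80
primateai_like_benign 0.48
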