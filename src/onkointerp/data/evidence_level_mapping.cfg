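# Harmonized mapping of source-specific clinical evidence codes to
# AMP/ASCO/CAP tier letters (A-D), following the cross-knowledgebase
# harmonization approach of Wagner et al. (meta-knowledgebase).
# Format: <source> <raw code> <tier letter>
# Edit or replace this file to change the mapping; unmapped codes are
# reported with the tier left unset (never an error).

civic_like A A
civic_like B B
civic_like C C
civic_like D D
civic_like E D

oncokb_like 1 A
oncokb_like 2 A
oncokb_like 3A B
oncokb_like 3B B
oncokb_like 4 D
oncokb_like R1 A
oncokb_like R2 C

metakb_like A A
metakb_like B B
metakb_like C C
metakb_like D D
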