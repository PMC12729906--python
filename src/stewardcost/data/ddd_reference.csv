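# Synthetic WHO-style defined-daily-dose reference (grams per DDD) for the
# 18 stewardship-targeted agents. Values are illustrative configuration in
# the spirit of the WHO ATC/DDD index, shipped so the pipeline runs
# end-to-end; sites should substitute the index version they report against.
# A blank route applies to all routes; a named route overrides it.
drug,route,ddd_grams
amikacin,,1.0
amphotericin,,0.035
anidulafungin,,0.1
aztreonam,,4.0
caspofungin,,0.05
cefepime,,4.0
ceftazidime,,4.0
ciprofloxacin,,1.0
ciprofloxacin,injectable,0.8
colistin,,0.72
daptomycin,,0.28
ertapenem,,1.0
fluconazole,,0.2
linezolid,,1.2
moxifloxacin,,0.4
posaconazole,,0.3
teicoplanin,,0.4
tigecycline,,0.1
voriconazole,,0.4
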