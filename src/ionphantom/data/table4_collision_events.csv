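ce_type,material,80,100,120,140,S.D.
vacancies,Water,25840000,29870000,33720000,37290000,4272452
vacancies,PMMA,20800000,24070000,27280000,30290000,3542563
vacancies,PS,19060000,22220000,25200000,28040000,3346117
vacancies,ST,16680000,19310000,21920000,24360000,2868200
vacancies,Resin,19780000,22970000,26010000,28960000,3419481
vacancies,Epoxy,19580000,22730000,25790000,28660000,3388385
displacements,Water,26270000,30370000,34290000,37920000,4347404
displacements,PMMA,21060000,24370000,27620000,30670000,3587276
displacements,PS,19390000,22610000,25630000,28530000,3404247
displacements,ST,16860000,19520000,22160000,24630000,2901735
displacements,Resin,19880000,23090000,26140000,29110000,3437372
displacements,Epoxy,19790000,22970000,26070000,28960000,3423101
replacements,Water,440000,510000,570000,630000,70489
replacements,PMMA,260000,300000,340000,380000,44721
replacements,PS,330000,390000,440000,490000,59319
replacements,ST,180000,210000,240000,260000,30311
replacements,Resin,100000,120000,130000,150000,18028
replacements,Epoxy,210000,240000,280000,310000,38079
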