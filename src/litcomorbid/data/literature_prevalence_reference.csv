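disease,this_study_pct,this_study_ci,literature_range_pct
Autoimmune thyroiditis,12.6,"10.1-14.9","1.4-30.2"
Type 1 diabetes mellitus,2.3,"1.2-3.4","2.2-6.5"
Dermatitis herpetiformis,2.0,"1.0-3.0","3.1-13.54"
Rheumatoid disease,0.9,"0.3-1.6","0.7-4.5"
Autoimmune hepatitis,0.9,"0.3-1.6","0.0-1.2"
Sjogren's syndrome,0.8,"0.2-1.5","0.2-3.3"
Addison's disease,0.4,"0.1-1.2","0.2-0.6"
Systemic lupus,0.3,"0.1-1.0","0.2-1.1"
Multiple sclerosis,0.1,"0.0-0.8","0.1-0.1"
Antiphospholipid syndrome,0,"0.0-0.5","0.2-0.2"
Myasthenia gravis,0,"0.0-0.5","0.2-0.2"
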