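dui,name,n_cases,printed_per_1000,printed_ci_low,printed_ci_high,wilson_flag
D013967,Autoimmune thyroiditis,93,125.5,101,149,false
D003922,Type 1 diabetes mellitus,17,22.9,12.1,33.5,false
D003874,Dermatitis herpetiformis,15,20.2,10,30.2,false
D001172,Rheumatoid arthritis,7,9.4,2.5,16.3,false
D019693,Autoimmune hepatitis,7,9.4,2.5,16.3,false
D006111,Graves' disease,6,8.1,1.6,14.5,false
D012859,Sjogren's syndrome,6,8.1,1.6,14.5,false
D000224,Addison disease,3,4,1.4,11.8,false
D008180,Systemic lupus erythematosus,2,2.7,0.7,9.8,true
D001171,Juvenile arthritis,1,1.3,0.1,7.6,true
D009103,Multiple sclerosis,1,1.3,0.1,7.6,true
D016884,Autoimmune Polyendocrinopathies,1,1.3,0.1,7.6,true
D016736,Antiphospholipid syndrome,0,0,0,5.2,true
D009157,Myasthenia gravis,0,0,0,5.2,true
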