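dui,name,n_cooccurrence,icd
D003922,"Diabetes Mellitus, Type 1",523,E10*
D003874,Dermatitis Herpetiformis,478,L130
D013967,"Thyroiditis, Autoimmune",96,E063
D001172,"Arthritis, Rheumatoid",87,M069*
D008180,"Lupus Erythematosus, Systemic",73,M32*
D009103,Multiple Sclerosis,44,G35
D012859,Sjogren's Syndrome,43,M350
D000224,Addison Disease,42,E271|E272
D001171,"Arthritis, Juvenile",37,M089*
D019693,"Hepatitis, Autoimmune",35,K754
D006111,Graves' Disease,30,E050|E05*
D005922,"Glomerulonephritis, IGA",27,N0330|N0170
D009157,Myasthenia Gravis,22,G700
D016884,"Polyendocrinopathies, Autoimmune",15,E31*
D016736,Antiphospholipid Syndrome,12,D686*
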