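name,fluid,units,source_header
kidney_mass,tissue,g,Kidney mass (g)
kidney_body_mass_ratio,derived,dimensionless,Kidney/ Body mass
ngal_serum,serum,μg/mL,"NGAL, serum (μg/mL)"
ngal_urine,urine,μg per 24 h,"NGAL, urine (μg)"
kim1_urine,urine,μg per 24 h,"Kim-1, urine (μg)"
cystatin_c_serum,serum,μg/mL,"Cystatin C, serum (μg/mL)"
cystatin_c_urine,urine,μg per 24 h,"Cystatin C, urine (μg)"
il18_serum,serum,μg/mL,"IL-18, serum (μg/mL)"
il18_urine,urine,μg per 24 h,"IL 18, urine (μg)"
scr,serum,mg/dL,SCr (mg/dL)
bun,serum,mg/dL,BUN (mg/dL)
proteinuria,urine,mg per 24 h,Proteinuria (mg)
microalbuminuria,urine,μg per 24 h,Microalbuminurua (μg)
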