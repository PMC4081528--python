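epithelium,P_D_1e-5_cm_s,P_f_1e-4_cm_s,ratio_Pf_Pd,aqp5_reference,citation_key
lung alveolar epithelium,1.30,170.0,1307.69,1,alveolar
corneal epithelium,1.68,,,1,cornea
cochlear duct epithelium,8.18,6.15,7.52,1,this_study_cde
conjunctival epithelium,13,11,8.46,1,conjunctiva
salivary gland acinar epithelium,300,2001.0,6.67,1,salivary
kidney cortical collecting duct,,,2.03,0,kidney_ccd
kidney proximal convoluted tubule,,5000,,0,kidney_pct
outer sulcus cells (cochlear apex),64.83,1569.0,242.02,0,this_study_osc
MDCK type I monolayer,,,1.0,0,mdck
phospholipid bilayer membrane,,,1.0,0,bilayer
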