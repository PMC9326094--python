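subject_id,group_label,labored_breathing,abnormal_auscultation,mucus_score,tracheal_neut_gt20,wcs,macrophages,lymphocytes,neutrophils,eosinophils,mast_cells
H01,healthy,no,no,,,,63,33.5,1.5,0,2
H02,healthy,no,no,,,,47,48,4,0,1
H03,healthy,no,no,,,,49.5,43.5,5,0,2
H04,healthy,no,no,,,,44,53.5,0.5,0,2
H05,healthy,no,no,,,,41,54,4.5,0,0.5
H06,healthy,no,no,,,,32.5,63,3.5,0,1
H07,healthy,no,no,,,,44.5,50.5,3,0,2
H08,healthy,no,no,,,,34.5,61.5,3.5,0,0.5
H09,healthy,no,no,,,,47,45.5,5.5,0,2
H10,healthy,no,no,,,,44,53,1.5,0,1.5
H11,healthy,no,no,,,,39.5,50,8,0.5,2
H12,healthy,no,no,,,,42.5,53,4,0,0.5
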