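subject_id,group_label,labored_breathing,abnormal_auscultation,mucus_score,tracheal_neut_gt20,wcs,macrophages,lymphocytes,neutrophils,eosinophils,mast_cells
S01,severe,yes,no,4,yes,10,42,33,24,0,1
S02,severe,no,yes,5,yes,9,27.5,30.5,40,0,2
S03,severe,yes,yes,5,yes,23,4,4,92,0,0
S04,severe,yes,yes,4,yes,14,26.5,50.5,14,0,9
S05,severe,yes,no,2,yes,7,54,24,20,0,2
S06,severe,no,no,3,yes,6,34,23,43,0,0
S07,severe,yes,no,3,yes,8,39,25,35,0,1
S08,severe,yes,no,4,yes,5,22,29,49,0,3
S09,severe,no,yes,4,yes,6,23,47.5,28,0,1.5
S10,severe,no,yes,5,yes,13,17,10,73,0,0
S11,severe,yes,no,4,yes,6,34.5,22.5,42,0,1
S12,severe,no,yes,5,yes,8,34.5,18,46,0,1.5
S13,severe,yes,no,3,yes,5,30,44,25,0,1
S14,severe,no,no,3,,4,19,57,24,0,0
M01,moderate,no,no,2,no,0,33.5,60.5,1.5,0,4.5
M02,moderate,no,no,2,no,0,34.5,48,15,0,2.5
M03,moderate,no,no,2,no,2,68,27,1,0,4
M04,moderate,no,no,2,no,3,51,28,19,0,2
M05,moderate,no,no,2,yes,0,42.5,40,14,0,3.5
M06,moderate,no,no,3,yes,1,45.5,46,8,0.5,0
M07,moderate,no,no,2,no,2,55,39,1,1.5,3.5
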