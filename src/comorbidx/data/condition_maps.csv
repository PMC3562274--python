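# ICD-10 to comorbidity-measure map. One row per condition; spans are
# semicolon-separated inclusive ranges at their printed granularity
# (3-character spans match by truncation). exact_spans list bare codes that
# match only literally (used where a bare 3-character code sits beside
# 4th-character subdivisions belonging to a different condition).
# CCI weights follow Charlson's recommendation (1/2/3/6); other measures are
# unweighted counts (weight 0).
measure,condition,weight,spans,exact_spans
FCI,Arthritis,0,M05.0-M05.9;M06.0-M06.9;M08.0-M08.9;M13.0-M13.9;M15.0-M19.9;M47.0-M47.9;M48.0;M48.9,
FCI,Osteoporosis,0,M80.0-M80.9;M81.0-M81.9;M82.0-M82.9;M83.0-M83.9,
FCI,Asthma,0,J45.0-J45.9,
FCI,COPD/ARDS,0,J43.0-J44.9,
FCI,Angina,0,I20.0-I20.9,
FCI,CHF or heart disease,0,I05.0-I07.9;I10.0-I11.9;I13.0-I15.9;I24.0-I24.9;I25.0-I25.1;I25.3-I25.9;I27.0-I27.9;I31.0-I31.9;I34.0-I35.9;I42.0-I42.9;I44.0-I46.9;I47.0-I51.9,
FCI,Heart attack,0,I21.0-I21.9;I22.0-I22.9;I25.2,
FCI,Neurological disease,0,G00.0-G99.9,
FCI,Stroke or TIA,0,I60.0-I64.9;G45.0-G45.9,
FCI,Diabetes,0,E10.0-E14.9,
FCI,Peripheral vascular disease,0,I73.9;I70.2,
FCI,Upper GI disease,0,K20.0-K22.9;K25.0-K31.9,
FCI,Depression,0,F32.0-F32.9;F33.0-F33.9,
FCI,Anxiety or panic disorders,0,F40.0-F40.9;F41.0-F41.9,
FCI,Visual impairment,0,H53.0-H54.9,
FCI,Hearing impairment,0,H90.0-H91.9,
FCI,Degenerative disc disease,0,M50.0-M51.9,
FCI,Obesity,0,E66.0-E66.9,
HAAGSMA,Chronic non-specific lung disease,0,J45.0-J45.9;J43.0-J44.9,
HAAGSMA,Heart disease,0,I05.0-I07.9;I10.0-I11.9;I13.0-I15.9;I24.0-I24.9;I25.0-I25.1;I25.3-I25.9;I27.0-I27.9;I31.0-I31.9;I34.0-I35.9;I42.0-I42.9;I44.0-I46.9;I47.0-I51.9;I20.0-I20.9;I21.0-I21.9;I22.0-I22.9;I25.2,
HAAGSMA,Diabetes,0,E10.0-E14.9,
HAAGSMA,Backache,0,M48.0;M51.0;M51.1;M51.3-M51.9;M54.3-M54.6;M54.9,
HAAGSMA,Osteoarthritis,0,M13.0-M13.9;M15.0-M19.9;M47.0-M47.9;M48.0;M48.9,
HAAGSMA,Rheumatoid arthritis,0,M05.0-M05.9;M06.0-M06.9;M08.0-M08.9,
HAAGSMA,Other disease or injury,0,A00.0-B99.9;C00.0-C97.9;D00.0-D48.9;D50.0-D58.9;E00.0-E07.0;E15.0-E90.9;F00.0-F99.9;G00.0-G99.9;H00.0-H59.9;H60.0-H95.9;I00.0-I99.9;J00.0-J39.9;J40.0-J42.9;J46.0-J99.9;K00.0-K93.9;L00.0-L99.9;M00.0-M03.9;M07.0-M07.9;M09.0-M12.9;M14.0-M14.9;M20.0-M46.9;M48.1-M48.8;M49.0-M99.9;N00.0-N99.9;O00.0-O99.9;P00.0-P96.9;Q00.0-Q99.9;R00.0-R99.9;S00.0-S99.9;T00.0-T98.9,
CCI,Myocardial infarction,1,I21-I24;I25.2;I25.8,
CCI,Congestive heart failure,1,I09;I11;I48;I49.0;I49.8;I50.0;I50.1;I50.9;I51.5;I97.1,
CCI,Peripheral vascular disease,1,I70;I71.1-I71.6;I71.8-I71.9;I72;I73;I74;I77,
CCI,Dementia,1,F00-F04;F05.1;F10,
CCI,Cerebrovascular disease,1,I60-I63;I65-I68;G45,
CCI,Chronic pulmonary disease,1,J41-J47,
CCI,Connective tissue disease,1,M05-M06;M08-M09;M12-M13;M30-M36,
CCI,Ulcer disease,1,K25-K28,
CCI,Mild liver disease,1,K70.0-K70.3;K70.9;K73;K74;K75.2-K75.9;K76.0-K76.5;K76.8-K76.9;K77,
CCI,Diabetes,1,E10.1;E10.5-E10.9;E11.1;E11.5-E11.9;E13.1;E13.5-E13.9;E14.1;E14.5-E14.9,E10;E11;E13;E14
CCI,Hemiplegia,2,G81.0-G81.1;G81.9;I63;I66-I67,
CCI,Moderate or severe renal disease,2,I12-I13;N00-N05;N17-N19,
CCI,Diabetes with end-organ damage,2,E10.2-E10.4;E11.2-E11.4;E13.2-E13.4;E14.2-E14.4,
CCI,Any tumour,2,D00-D48,
CCI,Leukaemia,2,C91-C95,
CCI,Lymphoma,2,C81-C85,
CCI,Moderate or severe liver disease,3,K70.4;K71.1;K71.7;K72;K75.0-K75.1;K76.6-K76.7,
CCI,Metastatic solid tumour,6,C00-C26;C30-C34;C37-C41;C43-C58;C60-C80;C88;C90;C96,
CCI,AIDS,6,B20-B24,
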