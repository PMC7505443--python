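code,description,category,subcategory,weight
PC-UTI-01,Lower urinary tract infection,uti,,
PC-UTI-02,Cystitis,uti,,
PC-UTI-03,Urinary tract infection NOS,uti,,
HX-UTI-01,Urinary tract infection (hospital),uti,,
HX-UTI-02,Acute cystitis (hospital),uti,,
PC-RUTI-01,Recurrent urinary tract infection,recurrent_uti,,
PC-SEP-01,Septicaemia,sepsis,unspecified,
PC-SEP-02,Bacteraemia,sepsis,unspecified,
HX-SEP-URO-01,Urosepsis,sepsis,urosepsis,
HX-SEP-RESP-01,Sepsis secondary to lower respiratory infection,sepsis,other_infectious:lower_respiratory,
HX-SEP-OTH-01,Sepsis of other infectious origin,sepsis,other_infectious:other,
HX-SEP-UNS-01,Sepsis unspecified organism,sepsis,unspecified,
PC-REF-01,Referral to specialist care,referral,,
PC-SMK-N-01,Never smoked tobacco,smoking_status,non,
PC-SMK-X-01,Ex-smoker,smoking_status,ex,
PC-SMK-C-01,Current smoker,smoking_status,current,
PC-CCI-MI-01,Myocardial infarction,comorbidity:myocardial_infarction,,1
PC-CCI-CHF-01,Congestive heart failure,comorbidity:congestive_heart_failure,,1
PC-CCI-PVD-01,Peripheral vascular disease,comorbidity:peripheral_vascular_disease,,1
PC-CCI-CVD-01,Cerebrovascular disease,comorbidity:cerebrovascular_disease,,1
PC-CCI-DEM-01,Dementia,comorbidity:dementia,,1
PC-CCI-COPD-01,Chronic pulmonary disease,comorbidity:chronic_pulmonary_disease,,1
PC-CCI-RHEUM-01,Rheumatologic disease,comorbidity:rheumatologic_disease,,1
PC-CCI-PUD-01,Peptic ulcer disease,comorbidity:peptic_ulcer_disease,,1
PC-CCI-LIVM-01,Mild liver disease,comorbidity:mild_liver_disease,,1
PC-CCI-DIAB-01,Diabetes without complications,comorbidity:diabetes,,1
PC-CCI-DIABC-01,Diabetes with chronic complications,comorbidity:diabetes_complications,,2
PC-CCI-PLEG-01,Hemiplegia or paraplegia,comorbidity:hemiplegia,,2
PC-CCI-RENAL-01,Renal disease,comorbidity:renal_disease,,2
PC-CCI-CANC-01,Any malignancy,comorbidity:malignancy,,2
PC-CCI-LIVS-01,Moderate or severe liver disease,comorbidity:severe_liver_disease,,3
PC-CCI-METS-01,Metastatic solid tumour,comorbidity:metastatic_tumour,,6
PC-CCI-AIDS-01,AIDS/HIV,comorbidity:aids,,6
HX-INF-RESP-01,Lower respiratory tract infection (hospital),other_infection,lower_respiratory,
HX-INF-SKIN-01,Skin and soft tissue infection (hospital),other_infection,other,
PC-OTH-01,Administrative encounter,none,,
HX-OTH-01,Non-infective hospital diagnosis,none,,
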