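patient_id,group,sex,age,disease_duration,cause_of_death
C-M-1,control,M,80,15 h,"Common bile duct stones, sepsis"
C-M-2,control,M,81,12-13 h,"Sigmoid colon perforation, acute generalized peritonitis"
C-M-3,control,M,83,23-24 h,Hemorrhagic cerebral infarction
C-M-4,control,M,83,23-24 h,"Cerebral hemorrhage, cerebral hernia"
C-M-5,control,M,87,12-13 h,"Hemorrhagic cerebral infarction, cerebral hernia"
C-M-6,control,M,89,2-3 h,(Lethal arrhythmia) Autopsy did not discover the cause of death
C-M-7,control,M,94,12-13 h,"Cerebral hemorrhage, cerebral hernia"
C-F-1,control,F,84,13 h,"Cerebral hemorrhage, cerebral hernia"
C-F-2,control,F,85,12-13 h,"Rectal perforation, acute generalized peritonitis"
C-F-3,control,F,86,10-11 h,"Acute myocardial infarction, cardiac tamponade"
C-F-4,control,F,86,16 h,Ruptured thoracic aortic aneurysm
C-F-5,control,F,89,1-2 h,"Aspiration pneumonia, food debris in bilateral main bronchi"
C-F-6,control,F,90,9 h,"Acute myocardial infarction, cardiac tamponade"
C-F-7,control,F,94,1 h,Airway obstruction with mucus and food debris
P-M-1,PCI,M,71,1 month,Gastric cancer with multiple metastases
P-M-2,PCI,M,72,46 days,Fulminant myocarditis
P-M-3,PCI,M,73,3 months,Pancreatic cancer with multiple metastases
P-M-4,PCI,M,74,7 months,"Sigmoid colon cancer, gastrointestinal hemorrhage"
P-M-5,PCI,M,74,1 year,Acute myeloid leukemia with myelodysplasia-related changes
P-M-6,PCI,M,81,1 month,"Aspiration pneumonia, lung abscess, sepsis"
P-M-7,PCI,M,81,21 days,"Chronic hepatitis, aspiration pneumonia, diffuse alveolar damage"
P-M-8,PCI,M,86,3 months,"Subcutaneous abscess, sepsis"
P-M-9,PCI,M,88,37 days,"Prostate cancer, pyelonephritis, sepsis"
P-M-10,PCI,M,88,5 months,"Ischemic enteritis, gastrointestinal hemorrhage, aspiration pneumonia"
P-F-1,PCI,F,77,1 month,Hepatitis C-related liver cirrhosis
P-F-2,PCI,F,78,21 days,Intra-abdominal hemorrhage following pancreaticoduodenectomy
P-F-3,PCI,F,86,5 months,"Pancreatic cancer with multiple metastases, bronchopneumonia, diffuse alveolar damage"
P-F-4,PCI,F,86,40 days,"Bronchopneumonia, lung abscess, bilateral pleural effusions, sepsis"
P-F-5,PCI,F,86,2 months,"Diabetic nephropathy, old myocardial infarction, bilateral pleural effusions, pulmonary edema"
P-F-6,PCI,F,87,2 months,"Hepatitis C, idiopathic portal hypertension, ruptured gastric varices"
P-F-7,PCI,F,90,28 days,"Myelodysplastic syndrome, pancytopenia"
P-F-8,PCI,F,95,1 month,"Aortic valve infective endocarditis, acute myocardial infarction"
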