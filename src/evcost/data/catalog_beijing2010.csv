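service_id,name,category,delivery_unit,in_nephsp,workload_urban,workload_suburban
clinic_visit,Clinic visit,basic_medical,per visit,False,15.00,15.00
emergency,Emergency,basic_medical,per visit,False,40.35,52.50
home_visit,Home visit,basic_medical,per visit,False,60.00,60.00
inpatient_bed_day,Inpatient bed day,basic_medical,per bed day,False,100.05,180.00
rehabilitation_clinic,Rehabilitation clinic,basic_medical,per outpatient visit,False,30.00,30.00
iv_injection,Intravenous injection,nursing,per procedure,False,7.50,6.00
iv_infusion,Intravenous infusion,nursing,per procedure,False,12.00,11.70
iv_blood_draw,Intravenous injection of venous blood,nursing,per procedure,False,9.30,9.45
catheterization,Catheterization,nursing,per procedure,False,28.95,19.50
prescription_western,Providing prescription (western medicine),nursing,per prescription,False,4.50,6.00
dispense_prescription,Providing medication to meet a prescription,pharmacy,per prescription,False,19.95,19.95
advanced_pharmacy,Advanced pharmacy work including detailed dosage calculations,pharmacy,per prescription,False,63.60,60.00
rapid_blood_sugar,Rapid blood sugar test,auxiliary_exam,per test,False,4.50,4.65
blood_urine_feces,"Blood, urine, feces test",auxiliary_exam,per test,False,9.00,9.15
biochemical_test,Biochemical test,auxiliary_exam,per test,False,30.00,27.45
electrocardiogram,Electrocardiogram,auxiliary_exam,per test,False,11.25,10.05
b_ultrasound,B-mode ultrasonography,auxiliary_exam,per test,False,19.95,19.95
health_records,Health records management service,nephsp,per person year,True,1019.25,972.00
health_education,Health education service,nephsp,per center,True,47076.00,34650.00
child_health,Health services for children aged 0 to 36 months,nephsp,per person year,True,173.40,203.40
maternal_health,Maternal health services,nephsp,per person year,True,210.00,262.50
older_people_health,Older people's health services,nephsp,per person year,True,60.00,49.95
immunizations,Immunizations,nephsp,per visit,True,25.05,15.45
infectious_disease,Infectious disease reporting and treatment,nephsp,per time,True,5913.63,4979.40
hypertension_mgmt,Health services for patients with hypertension,nephsp,per person year,True,190.05,152.55
diabetes_mgmt,Services for patients with type II diabetes,nephsp,per person year,True,190.05,147.45
mental_illness_mgmt,Services for patients with severe mental illness,nephsp,per person year,True,472.50,420.00
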