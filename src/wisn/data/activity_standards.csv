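cadre,activity,category,time_value,time_unit
Nurse/Midwife,Antenatal care,core,10,minutes_per_client
Nurse/Midwife,Delivery,core,60,minutes_per_client
Nurse/Midwife,Postnatal care,core,14,minutes_per_client
Nurse/Midwife,Family planning (counselling),core,18,minutes_per_client
Nurse/Midwife,Family planning (insertion of IUCD),core,20,minutes_per_client
Nurse/Midwife,Family planning (insertion of an implant),core,17,minutes_per_client
Nurse/Midwife,Family planning (injection),core,7,minutes_per_client
Nurse/Midwife,Family planning (oral pills),core,7,minutes_per_client
Nurse/Midwife,Immunization,core,9,minutes_per_client
Nurse/Midwife,Diarrhoea in U5 years old,core,14,minutes_per_client
Nurse/Midwife,Pneumonia in U5 years old,core,15,minutes_per_client
Nurse/Midwife,Confirmed uncomplicated malaria,core,18,minutes_per_client
Nurse/Midwife,Community mobilisation and education,support,0,hours_per_week
Nurse/Midwife,Ward development committee meetings,support,51,minutes_per_month
Nurse/Midwife,Outreaches/community-based services,support,0,hours_per_week
Nurse/Midwife,Hand over/report writing,support,36,minutes_per_week
Nurse/Midwife,Staff meetings,support,38,minutes_per_week
Nurse/Midwife,Documentation on patients,support,30,minutes_per_day
Nurse/Midwife,Group health education,support,40,minutes_per_week
Nurse/Midwife,Supervision of students,individual,60,minutes_per_day
Nurse/Midwife,General administration,individual,50,minutes_per_day
Nurse/Midwife,Monthly report writing,individual,50,minutes_per_month
Nurse/Midwife,Review meetings,individual,2,hours_per_month
Nurse/Midwife,Mentoring of subordinates,individual,44,minutes_per_day
Nurse/Midwife,Facility management meeting,individual,51,minutes_per_month
Nurse/Midwife,Sterilisation of equipment,individual,5,minutes_per_day
CHW,Antenatal care,core,10,minutes_per_client
CHW,Delivery,core,60,minutes_per_client
CHW,Postnatal care,core,19,minutes_per_client
CHW,Family planning (counselling),core,17,minutes_per_client
CHW,Family planning (insertion of IUCD),core,17,minutes_per_client
CHW,Family planning (insertion of an implant),core,13,minutes_per_client
CHW,Family planning (injection),core,8,minutes_per_client
CHW,Family planning (oral pills),core,9,minutes_per_client
CHW,Immunization,core,11,minutes_per_client
CHW,Diarrhoea in U5 years old,core,13,minutes_per_client
CHW,Pneumonia in U5 years old,core,14,minutes_per_client
CHW,Confirmed uncomplicated malaria,core,21,minutes_per_client
CHW,Community mobilisation and education,support,2,hours_per_week
CHW,Ward development committee meetings,support,50,minutes_per_month
CHW,Outreaches/community-based services,support,2,hours_per_week
CHW,Hand over/report writing,support,25,minutes_per_week
CHW,Staff meetings,support,33,minutes_per_week
CHW,Documentation on patients,support,30,minutes_per_day
CHW,Group health education,support,31,minutes_per_week
CHW,Supervision of students,individual,60,minutes_per_day
CHW,General administration,individual,66,minutes_per_day
CHW,Monthly report writing,individual,69,minutes_per_month
CHW,Review meetings,individual,3,hours_per_month
CHW,Mentoring of subordinates,individual,36,minutes_per_day
CHW,Facility management meeting,individual,39,minutes_per_month
CHW,Sterilisation of equipment,individual,4,minutes_per_day
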