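facility,cadre,available,required,gap,ratio
Doka (Zakari Isah) Primary Health Care Centre,Nurse/Midwife,1,3,-2,0.33
Doka (Zakari Isah) Primary Health Care Centre,CHW,9,5,4,1.80
Junction Road Primary Health Care Centre,Nurse/Midwife,1,3,-2,0.33
Junction Road Primary Health Care Centre,CHW,5,5,0,1.00
PHC Clinic Jos Road,Nurse/Midwife,1,1,0,1.00
PHC Clinic Jos Road,CHW,1,2,-1,0.50
Primary Health Care Badarawa,Nurse/Midwife,1,3,-2,0.33
Primary Health Care Badarawa,CHW,14,5,9,2.80
Primary Health Care Centre Hayin Banki,Nurse/Midwife,1,11,-10,0.09
Primary Health Care Centre Hayin Banki,CHW,3,26,-23,0.12
Primary Health Care Centre Kabala,Nurse/Midwife,1,5,-4,0.20
Primary Health Care Centre Kabala,CHW,5,13,-8,0.38
Primary Health Care Centre Unguwar Rimi,Nurse/Midwife,1,8,-7,0.13
Primary Health Care Centre Unguwar Rimi,CHW,5,20,-15,0.25
Primary Health Centre Unguwar Shanu,Nurse/Midwife,0,11,-11,0.00
Primary Health Centre Unguwar Shanu,CHW,4,24,-20,0.17
Primary Health Centre Mohammed Bello Tukur Memorial,Nurse/Midwife,1,3,-2,0.33
Primary Health Centre Mohammed Bello Tukur Memorial,CHW,3,6,-3,0.50
Primary Health Centre Unguwar Sarki,Nurse/Midwife,1,6,-5,0.17
Primary Health Centre Unguwar Sarki,CHW,2,15,-13,0.13
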