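pair_id,risk_factor,outcome,deaths_2000,deaths_2010,deaths_2016,deaths_rate100k_2000,deaths_rate100k_2010,deaths_rate100k_2016,daly_2000,daly_2010,daly_2016,daly_rate100k_2000,daly_rate100k_2010,daly_rate100k_2016
asbestos_tbl_cancer,Occupational exposure to asbestos,"Trachea, bronchus and lung cancers",137786,169697,177614,3.2,3.4,3.2,2804297,3197063,3286180,65.8,63.4,59.9
asbestos_ovary_cancer,Occupational exposure to asbestos,Ovary cancer,4519,5214,5464,0.1,0.1,0.1,91953,99889,104297,2.2,2.0,1.9
asbestos_larynx_cancer,Occupational exposure to asbestos,Larynx cancer,2933,3079,3299,0.1,0.1,0.1,67006,66073,69564,1.6,1.3,1.3
asbestos_mesothelioma,Occupational exposure to asbestos,Mesothelioma,12703,20567,23104,0.3,0.4,0.4,327763,476621,513810,7.7,9.4,9.4
arsenic_tbl_cancer,Occupational exposure to arsenic,"Trachea, bronchus and lung cancers",5651,6893,7589,0.1,0.1,0.1,183316,218684,236361,4.3,4.3,4.3
benzene_leukemia,Occupational exposure to benzene,Leukemia,1175,1304,1452,0.0,0.0,0.0,73681,76947,85022,1.7,1.5,1.6
beryllium_tbl_cancer,Occupational exposure to beryllium,"Trachea, bronchus and lung cancers",101,138,165,0.0,0.0,0.0,4971,6442,7181,0.1,0.1,0.1
cadmium_tbl_cancer,Occupational exposure to cadmium,"Trachea, bronchus and lung cancers",279,392,452,0.0,0.0,0.0,11696,15292,17172,0.3,0.3,0.3
chromium_tbl_cancer,Occupational exposure to chromium,"Trachea, bronchus and lung cancers",620,884,1022,0.0,0.0,0.0,23888,31779,36059,0.6,0.6,0.7
diesel_exhaust_tbl_cancer,Occupational exposure to diesel engine exhaust,"Trachea, bronchus and lung cancers",9116,12709,14728,0.2,0.3,0.3,303473,410674,470650,7.1,8.1,8.6
formaldehyde_nasopharynx_cancer,Occupational exposure to formaldehyde,Nasopharynx cancer,263,294,327,0.0,0.0,0.0,16082,16894,18056,0.4,0.3,0.3
formaldehyde_leukemia,Occupational exposure to formaldehyde,Leukemia,350,372,416,0.0,0.0,0.0,26657,26912,29143,0.6,0.5,0.5
nickel_tbl_cancer,Occupational exposure to nickel,"Trachea, bronchus and lung cancers",5449,6641,7301,0.1,0.1,0.1,178881,212860,229980,4.2,4.2,4.2
pah_tbl_cancer,Occupational exposure to polycyclic aromatic hydrocarbons,"Trachea, bronchus and lung cancers",2428,3364,3881,0.1,0.1,0.1,84081,111823,126900,2.0,2.2,2.3
silica_tbl_cancer,Occupational exposure to silica,"Trachea, bronchus and lung cancers",31910,38608,42258,0.7,0.8,0.8,1022981,1207501,1302917,24.0,23.9,23.8
sulfuric_acid_larynx_cancer,Occupational exposure to sulfuric acid,Larynx cancer,2227,2303,2564,0.1,0.0,0.0,81783,83960,91636,1.9,1.7,1.7
trichloroethylene_kidney_cancer,Occupational exposure to trichloroethylene,Kidney cancer,6,18,25,0.0,0.0,0.0,1249,1877,2343,0.0,0.0,0.0
asthmagens_asthma,Occupational asthmagens,Asthma,35293,30568,29641,0.8,0.6,0.5,2106628,2050770,2104429,49.4,40.6,38.4
particulates_copd,"Occupational particulate matter, gases and fumes",Chronic obstructive pulmonary disease,473725,431992,450381,11.1,8.6,8.2,11053935,10335238,10855103,259.4,204.8,197.9
noise_hearing_loss,Occupational noise,Other hearing loss,0,0,0,0.0,0.0,0.0,5917732,7280576,8164140,138.9,144.3,148.9
injuries_pedestrian_road,Occupational injuries,Pedestrian road injuries,78790,72032,72157,1.8,1.4,1.3,4547165,4214378,4244768,106.7,83.5,77.4
injuries_cyclist_road,Occupational injuries,Cyclist road injuries,10915,10521,12018,0.3,0.2,0.2,781662,802973,932514,18.3,15.9,17.0
injuries_motorcyclist_road,Occupational injuries,Motorcyclist road injuries,41945,44311,48151,1.0,0.9,0.9,2805094,2988019,3249277,65.8,59.2,59.2
injuries_motor_vehicle_road,Occupational injuries,Motor vehicle road injuries,67879,70268,76946,1.6,1.4,1.4,4120501,4261916,4639833,96.7,84.5,84.6
injuries_other_road,Occupational injuries,Other road injuries,1764,1807,1859,0.0,0.0,0.0,172682,198907,231259,4.1,3.9,4.2
injuries_other_transport,Occupational injuries,Other transport injuries,21597,17797,16864,0.5,0.4,0.3,1868380,1587934,1584940,43.8,31.5,28.9
injuries_poisoning_co,Occupational injuries,Poisoning by carbon monoxide,7408,4249,3772,0.2,0.1,0.1,411082,239498,213606,9.6,4.7,3.9
injuries_poisoning_other,Occupational injuries,Poisoning by other means,10477,6313,5330,0.2,0.1,0.1,626837,389740,340195,14.7,7.7,6.2
injuries_falls,Occupational injuries,Falls,36808,34064,34996,0.9,0.7,0.6,3535943,3472602,3726068,83.0,68.8,67.9
injuries_fire_heat,Occupational injuries,"Fire, heat and hot substances",16002,11342,10234,0.4,0.2,0.2,1201594,946261,920655,28.2,18.8,16.8
injuries_drowning,Occupational injuries,Drowning,33135,26779,26281,0.8,0.5,0.5,1956331,1559372,1530312,45.9,30.9,27.9
injuries_firearm,Occupational injuries,Unintentional firearm injuries,6348,5477,5079,0.1,0.1,0.1,424086,357843,344830,10.0,7.1,6.3
injuries_mechanical_forces,Occupational injuries,Other exposure to mechanical forces,21308,18121,17406,0.5,0.4,0.3,1900679,1765361,1798106,44.6,35.0,32.8
injuries_aspiration_airway,Occupational injuries,Pulmonary aspiration and foreign body in airway,8470,7942,7831,0.2,0.2,0.1,420613,383236,380882,9.9,7.6,6.9
injuries_foreign_body_other,Occupational injuries,Foreign body in other body part,794,635,649,0.0,0.0,0.0,163163,149381,165778,3.8,3.0,3.0
injuries_nonvenomous_animal,Occupational injuries,Non-venomous animal contact,1495,1161,1213,0.0,0.0,0.0,153866,125943,130080,3.6,2.5,2.4
injuries_venomous_animal,Occupational injuries,Venomous animal contact,9261,6535,6359,0.2,0.1,0.1,647679,484024,478692,15.2,9.6,8.7
injuries_other_unintentional,Occupational injuries,Other unintentional injuries,21478,17860,16138,0.5,0.4,0.3,1812672,1600309,1528257,42.5,31.7,27.9
ergonomic_back_neck_pain,Occupational ergonomic factors,Back and neck pain,0,0,0,0.0,0.0,0.0,10214925,11342041,12267159,239.7,224.8,223.7
long_hours_ihd,Exposure to long working hours,Ischemic heart disease,244844,304200,346618,7.9,6.0,6.3,7548225,9368428,10655256,177.1,185.7,194.3
long_hours_stroke,Exposure to long working hours,Stroke,334724,366524,398306,5.7,7.3,7.3,10352978,11471221,12603247,242.9,227.4,229.8
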