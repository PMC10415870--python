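study_id,treatment,n,change_mean,change_sd,baseline_mean,baseline_sd,final_mean,final_sd,population,duration_weeks
Christoph 2012,TZD,27,0.7,2.1,,,,,CAD,36
Christoph 2012,placebo,27,0.5,2.1,,,,,CAD,36
Antonio 2021,SGLT2i,42,-0.6,1.4,,,,,T2DM,24
Antonio 2021,placebo,42,0.6,1.2,,,,,T2DM,24
Ikonomidis 2020,GLP1RA,40,-1.1,2.4,,,,,T2DM,48
Ikonomidis 2020,SGLT2i,40,-1.1,2.5,,,,,T2DM,48
Stakos 2005,TZD,40,1.1,0.4,,,,,T2DM,48
Stakos 2005,placebo,97,0.7,0.4,,,,,T2DM,48
Lambadiari 2018,GLP1RA,30,-0.6,2.8,,,,,T2DM,24
Lambadiari 2018,metformin,30,-0.2,3.2,,,,,T2DM,24
Tuttolomondo 2021,GLP1RA,56,-0.3,0.8,,,,,T2DM,36
Tuttolomondo 2021,metformin,56,0.1,0.7,,,,,T2DM,36
Kato 2010,TZD,25,0.08,0.4,,,,,T2DM,12
Kato 2010,metformin,25,0.01,0.4,,,,,T2DM,12
Papadopoulou 2021,SGLT2i,43,-0.2,1.1,,,,,T2DM,12
Papadopoulou 2021,placebo,42,0.01,1.3,,,,,T2DM,12
deBoer 2021,DPP4i,22,-0.4,0.3,,,,,T2DM,26
deBoer 2021,placebo,22,0.4,0.3,,,,,T2DM,26
Kolwelter 2021,DPP4i,48,-0.3,1.6,,,,,CHF,12
Kolwelter 2021,placebo,26,0.3,1.7,,,,,CHF,12
Zografou 2015,DPP4i,32,-0.3,1.5,,,,,T2DM,24
Zografou 2015,metformin,32,0.2,1.8,,,,,T2DM,24
Paiman 2021,GLP1RA,22,0.2,2.1,,,,,T2DM,26
Paiman 2021,placebo,25,-0.2,1.7,,,,,T2DM,26
Kim 2008,TZD,45,-0.9,2.5,,,,,pre-T2DM,12
Kim 2008,placebo,40,0.02,2.0,,,,,pre-T2DM,12
Bjornstad 2018,metformin,24,-1.1,1.2,,,,,T1DM,12
Bjornstad 2018,placebo,21,4.1,1.6,,,,,T1DM,12
Scalzo 2017,sulfonylurea,13,-0.3,0.9,,,,,T2DM,12
Scalzo 2017,DPP4i,14,0.2,1.1,,,,,T2DM,12
Martin 2015,DPP4i,24,-0.1,1.2,,,,,T2DM,24
Martin 2015,sulfonylurea,24,-0.4,1.3,,,,,T2DM,24
Sofer 2021,metformin,32,-1.0,0.9,,,,,NAFLD,12
Sofer 2021,placebo,31,0.2,1.0,,,,,NAFLD,12
Watanabe 2004,TZD,13,-1.0,2.2,,,,,T2DM,24
Watanabe 2004,sulfonylurea,14,0.1,1.8,,,,,T2DM,24
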