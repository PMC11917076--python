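study_id,citation,diagnosis_label,first_wave_mean_age,n,percent_female,followup_length,n_waves,low_confidence
alsem2013,Alsem 2013,CP,2.50,92,41.30,2,3,
anderson2011,Anderson 2011,ASD,9.75,65,10.77,9,17,
auerbach2008,Auerbach 2008,Dyscalculia,11.10,29,51.72,6,3,
auerbach2008,Auerbach 2008,Dyscalculia-NP,11.10,29,51.72,6,3,
baribeau2021,Baribeau 2021,ASD,3.34,421,15.44,7,8,
biederman1996,Biederman 1996,ADHD,10.60,128,0.00,4,3,
ciciolla2014,Ciciolla 2014,Delay,3.00,110,32.73,2,3,
colvert2021,Colvert 2021,ASD,4.00,135,13.33,9,3,
cornish2012,Cornish 2012,Fragile X,8.17,48,0.00,2,3,
fieldinggebhardt2020,Fielding-Gebhardt 2020,Fragile X,9.13,55,20.00,7,3,
flouri2015,Flouri 2015,ASD,3.13,165,21.82,4,3,
flouri2015,Flouri 2015,ASD + ADHD,3.11,44,6.82,4,3,
gotham2015,Gotham 2015,DD,12.30,56,39.00,7,7,
green2005,Green 2005,DD,3.90,13,23.08,3,6,
harvey2015,Harvey 2015,ADHD,3.68,75,38.67,3,4,
hausercram2016,Hauser-Cram 2016,DD,3.00,169,46.15,15,5,
hickey2020,Hickey 2020,ASD,9.07,159,13.21,,3,
hogan2014,Hogan 2014,Hearing,4.75,93,,6,4,
holmbeck2010,Holmbeck 2010,Spina bifida,8.34,68,45.59,6,4,
horbach2020,Horbach 2020,SLD,6.21,27,33.33,5,5,
horbach2020,Horbach 2020,SLD + ADHD,6.21,15,26.67,5,5,
horbach2020,Horbach 2020,ADHD,6.21,13,30.77,5,5,
hoza2010,Hoza 2010,ADHD,9.97,513,20.27,6,4,
hunsche2020,Hunsche 2020,ASD,7.70,178,17.42,3,4,
kates2019,Kates 2019,22q11.2DS,11.87,87,47.13,9,4,
lahey2016,Lahey 2016,ADHD,5.24,125,14.40,12,13,
lahey2016,Lahey 2016,ADHD,9.24,125,14.40,8,9,
lahey2016,Lahey 2016,ADHD,10.24,125,14.40,7,8,
li2020,Li 2020,ASD,4.56,59,0.00,2,3,
lindsay2007,Lindsay 2007,SSLD,8.25,69,24.64,4,3,
midouhas2013,Midouhas 2013,ASD,3.00,209,16.75,4,3,
moskowitz2020,Moskowitz 2020,Fragile X,6.71,153,18.95,,5,
mrug2012,Mrug 2012,ADHD,10.35,300,20.00,6,3,
murrayclose2010,Murray-Close 2010,ADHD,10.00,536,18.66,6,4,
musser2016,Musser 2016,ADHD,9.53,388,30.93,2,3,
peverill2019,Peverill 2019,ASD,3.41,396,15.66,3,4,
rai2018,Rai 2018,ASD,10.00,96,17.71,8,6,
rosema2015,Rosema 2015,TBI mild,5.19,13,46.15,16,5,
rosema2015,Rosema 2015,TBI moderate,4.89,40,70.00,17,5,followup_length
rosema2015,Rosema 2015,TBI severe,5.09,22,63.64,17,5,followup_length
sigafoos2000,Sigafoos 2000,DD,3.90,13,23.08,3,6,
sipal2010,Sipal 2010,CP,11.23,110,36.36,3,4,
stclair2011,St Clair 2011,SLI,7.00,234,23.50,9,4,
steinhausen2003,Steinhausen 2003,ADHD,10.20,35,17.14,3,3,
stringer2020,Stringer 2020,ASD,11.60,158,10.13,12,3,
tan2014,Tan 2014,CP 1-4 y,1.50,97,44.33,3,4,
tan2014,Tan 2014,CP 5-8 y,6.25,116,34.48,2,3,
tan2014,Tan 2014,CP 9-15 y,11.00,108,37.04,3,4,
vaillancourt2017,Vaillancourt 2017,ASD,3.19,392,15.56,3,4,
vankeer2021,Van keer 2021,SDD,3.10,25,68.00,2,3,
vaughn1993,Vaughn 1993,LD,6.00,10,40.00,3,4,
vaughn1994,Vaughn 1994,LD,6.00,10,40.00,5,5,
wall2019,Wall 2019,Fragile X,0.51,116,25.00,4,8,
wei2014,Wei 2014,LD,11.59,722,38.37,3,3,
wei2014,Wei 2014,LD + ADHD,11.63,303,20.13,3,3,
wei2014,Wei 2014,ADHD + ED,11.17,569,14.94,3,3,
williams2016,Williams 2016,ADHD,0.70,112,25.00,6,4,
williams2016,Williams 2016,ADHD-S,0.74,648,35.65,6,4,
woodman2015,Woodman 2015,DD,3.00,176,44.89,15,5,
woodruffborden2010,Woodruff-Borden 2010,WS,6.67,45,53.33,4,9,
yeates2006,Yeates 2006,TBI severe,9.90,53,26.42,4,3,
yeates2006,Yeates 2006,TBI moderate,10.50,56,26.79,4,3,
zendarski2021,Zendarski 2021,ADHD,10.70,130,0.00,3,3,
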