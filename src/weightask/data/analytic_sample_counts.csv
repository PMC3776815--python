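section,row,male_skinny,male_thin,male_fat,male_obese,female_skinny,female_thin,female_fat,female_obese
age,13-15,38,73,277,54,96,253,812,105
age,16-18,22,58,319,26,32,148,351,43
age,19-25,10,121,271,19,20,87,399,39
age,25+,2,4,92,4,4,24,113,10
adult_bmi,<18.5,4,87,3,0,10,23,28,0
adult_bmi,18.5-25,4,19,93,2,7,44,236,6
adult_bmi,25-30,0,5,107,4,2,10,78,7
adult_bmi,30+,0,4,83,12,2,11,72,26
teen_pct,<5,15,16,24,0,18,46,62,1
teen_pct,5-85,42,83,334,17,95,311,882,52
teen_pct,85-95,4,17,156,13,11,45,201,37
teen_pct,95+,3,25,159,55,7,22,116,68
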