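study_id,variable,level_a,a_m,a_n,level_b,b_m,b_n
wang2006,stage,III/IV,30,32,I/II,33,39
xing2013,age,>=60,4,7,<60,23,28
xing2013,stage,III/IV,22,24,I/II,5,11
xing2013,histology,serous,22,26,others,5,9
xing2013,grade,poorly differentiated,19,21,well/moderately differentiated,8,14
zhou2013_tissues,stage,III/IV,34,35,I/II,5,10
zhou2013_tissues,histology,serous,18,20,others,21,25
zhou2013_tissues,grade,poorly differentiated,29,29,well/moderately differentiated,10,16
zhou2013_serum,stage,III/IV,31,35,I/II,5,10
zhou2013_serum,histology,serous,17,20,others,19,25
zhou2013_serum,grade,poorly differentiated,27,29,well/moderately differentiated,9,16
zhou2014,age,>=55,41,48,<55,39,54
zhou2014,stage,III/IV,49,58,I/II,31,44
zhou2014,histology,serous,42,57,others,38,45
czekierdowski2006,stage,III/IV,16,38,I/II,4,5
czekierdowski2006,histology,serous,8,15,others,12,28
czekierdowski2006,grade,poorly differentiated,9,23,well/moderately differentiated,11,20
liu2011,stage,III/IV,16,41,I/II,2,22
liu2011,histology,serous,20,34,others,10,29
liu2011,grade,poorly differentiated,12,27,well/moderately differentiated,6,36
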