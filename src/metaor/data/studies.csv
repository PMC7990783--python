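study_id,article_id,year,country,sample_type,control_type,method,case_m,case_u,ctrl_m,ctrl_u
wang2006,wang2006,2006,China,serum,NT&BOT,MSP,64,7,11,112
xing2013,xing2013,2013,China,tissues,NT,CCP-based FRET,27,8,2,9
zhou2013_tissues,zhou2013,2013,China,tissues,NT,restriction-enzyme,39,6,0,40
zhou2013_serum,zhou2013,2013,China,serum,NT,restriction-enzyme,36,9,0,20
zhou2014,zhou2014,2014,China,tissues,NT&BOT,MSP,80,22,28,87
czekierdowski2006,czekierdowski2006,2006,Poland,tissues,NT,MSP,20,23,0,4
zhang2006,zhang2006,2006,China,tissues,NT&BOT,restriction-enzyme,32,40,0,37
liu2011,liu2011,2011,China,tissues,AT&NT,MSP,30,33,2,33
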