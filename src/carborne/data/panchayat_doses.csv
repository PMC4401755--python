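panchayat,n,mean_msv_y,max_msv_y,min_msv_y,median_msv_y,radiation_level
Alappad,136,1.9,5.1,0.4,1.9,High
Chavara,214,1.2,13,0.5,0.9,High
Clappana,50,0.8,1.1,0.6,0.8,Middle
Karunagappally,112,0.9,1.6,0.5,0.9,Middle
K. S. Puram,74,0.8,1.1,0.5,0.9,Middle
Neendakara,125,2.3,12,0.6,1.5,High
Oachira,115,0.6,1.5,0.2,0.5,Low
Panmana,273,1.1,2.9,0.6,1,High
Thazhava,138,0.6,0.8,0.5,0.6,Low
Thekkumbhagam,112,1.1,4.3,0.4,0.9,Middle
Thevalakkara,215,0.7,1,0.5,0.7,Low
Thodiyoor,109,0.7,0.9,0.5,0.7,Low
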