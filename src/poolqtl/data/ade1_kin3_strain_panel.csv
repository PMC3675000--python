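strain,169227,170564,170852,170945,171947
Kyokai_no7,T,G,C,A,C
EC9-8,C,G,C,A,C
Lalvin_QA23,C,A,C,A,C
VIN13,C,A,C,A,C
JAY291,C,A,C,A,C
L1528,C,A,C,A,C
ForstersB,C,both,C,A,C
Forsters0,C,G,C,A,C
AWRI_1631,C,A,C,A,C
AWRI_796,C,A,C,A,C
UC5,T,G,C,A,C
YPS128,C,A,C,A,C
T7,C,A,C,G,C
YJSH1,C,G,C,G,C
ZTW1,C,G,C,A,C
Y12,C,G,C,G,C
VL3,C,A,C,A,C
CBS_7960,C,A,C,A,C
T73,C,A,C,A,C
DBVPF1106,C,A,C,A,C
PW5,C,G,C,G,C
Sigma1278b,C,G,C,G,C
RM11-1a,C,A,C,A,C
CEN.PK113-7D,C,G,C,A,C
Y55,C,G,C,G,C
W303,C,G,C,A,C
SK1,C,G,C,G,C
UWOPS83-787_3,C,A,C,G,C
UWOPS03-461.4,C,A,C,A,C
UWOPS87-2421,C,G,C,G,C
DBVPG1373,C,A,C,A,C
DBVPG6044,C,G,C,G,C
DBVPG6765,C,A,C,A,C
YJM789,C,A,C,A,C
YJM975,C,A,C,A,C
YJM269,C,A,C,A,C
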