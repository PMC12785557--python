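tma_spot,case_id,specimen_id,race,stage,metastatic,year,histology_grade,gleason_pattern,wt_score,tr_score
B2,40,1012050,White,2B,Non-Meta,2011,Adenocarcinoma III P,034,4,4
B5,41,1012216,White,2B,Non-Meta,2011,Adenocarcinoma III P,033,3,3
B6,42,1012220,White,2B,Non-Meta,2011,Adenocarcinoma III P,034,2,4
B9,43,1012335,White,2B,Non-Meta,2011,Adenocarcinoma III P,034,3,3
B10,44,1012402,White,2B,Non-Meta,2011,Adenocarcinoma III P,034,2,4
C6,47,1013484,White,4,,2012,Adenocarcinoma III P,045,5,4
C9,48,1014164,Black,3,Non-Meta,2013,Adenocarcinoma III P,044,4,4
D2,50,1015479,Black,3,,2014,Adenocarcinoma II M,034,6,3
D5,51,1015775,Black,3,,2014,Adenocarcinoma,034,3,3
D6,52,1015805,Black,3,Non-Meta,2014,Adenocarcinoma II M,034,8,5
D8,53,1015945,Black,3,,2014,Adenocarcinoma III P,044,3,3
D10,54,1017035,White,4,,2015,Adenocarcinoma III P,044,4,1
E5,56,1017270,White,4,,2015,Adenocarcinoma III P,044,5,3
E6,57,1017534,White,4,,2015,Adenocarcinoma III P,044,3,3
E9,58,1017541,Black,3,Non-Meta,2015,Adenocarcinoma III P,043,3,3
F5,61,1017903,White,4,,2016,Adenocarcinoma III P,034,3,3
G3,65,1019042,White,4,,2017,Adenocarcinoma III P,054,4,2
G4,66,1019132,White,4,C0,2017,Adenocarcinoma III P,045,3,3
H2,70,1019428,White,4,,2017,Adenocarcinoma III P,054,6,2
H6,72,1019693,White,3,c0,2017,Adenocarcinoma III P,045,4,2
I3,75,1020025,White,4,c1B,2017,Adenocarcinoma III P,045,4,1
I6,77,1020766,Black,4A,p1,2018,Adenocarcinoma III P,045,30,13
I9,78,1022418,Black,4A,p1,2020,Adenocarcinoma III P,053,7,1
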