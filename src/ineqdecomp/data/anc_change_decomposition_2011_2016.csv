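label,v1_dC,v1_dZ,v2_dC,v2_dZ,total,percent
age[25-34],-0.0003,-0.0020,-0.0002,-0.0022,-0.0023,-8.19
age[35-49],-0.0043,0.0032,-0.0027,0.0016,-0.0011,-3.90
wealth[poorer],0.0026,0.0044,0.0016,0.0054,0.0070,24.24
wealth[middle],0.0052,-0.0042,0.0027,-0.0017,0.0010,3.39
wealth[richer],0.0032,-0.0119,0.0024,-0.0110,-0.0087,-30.19
wealth[richest],0.0003,0.0128,0.0004,0.0127,0.0131,45.66
head[female],0.0009,0.0001,0.0006,0.0004,0.0010,3.45
marital[married],0.0003,-0.0008,0.0000,-0.0004,-0.0005,-1.69
residence[rural],-0.0081,-0.0021,-0.0037,-0.0065,-0.0102,-35.64
zone[hills],0.0004,0.0040,0.0015,0.0030,0.0044,15.45
zone[terai],-0.0030,0.0070,-0.0020,0.0060,0.0040,13.88
religion[buddhist],-0.0003,0.0013,0.0012,-0.0001,0.0011,3.70
religion[muslim],0.0006,0.0007,-0.0003,0.0016,0.0013,4.44
religion[kirat],0.0001,-0.0002,0.0000,-0.0002,-0.0001,-0.36
religion[christian],-0.0007,0.0002,-0.0005,0.0000,-0.0005,-1.78
education[primary],0.0046,0.0003,0.0042,0.0007,0.0049,17.05
education[secondary],0.0456,-0.0236,0.0278,-0.0058,0.0220,76.61
education[higher],0.0419,-0.0810,0.0122,-0.0514,-0.0392,-136.48
partner_education[educated],0.0070,0.0003,0.0072,0.0001,0.0073,25.42
occupation[working],0.0014,0.0084,0.0005,0.0093,0.0098,34.16
distance[problem],0.0019,0.0025,0.0025,0.0019,0.0044,15.30
children,0.0143,-0.0085,0.0115,-0.0057,0.0058,20.20
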