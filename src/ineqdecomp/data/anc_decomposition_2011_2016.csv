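label,group,zeta_2011,ci_2011,contrib_2011,zeta_2016,ci_2016,contrib_2016
age[25-34],age,-0.0441,0.0547,-0.0024,-0.0809,0.0589,-0.0048
age[35-49],age,-0.0165,-0.3176,0.0052,-0.0266,-0.1546,0.0041
wealth[poorer],wealth,-0.0234,-0.3112,0.0073,-0.0376,-0.3791,0.0142
wealth[middle],wealth,-0.0385,0.1160,-0.0045,-0.0746,0.0468,-0.0035
wealth[richer],wealth,-0.0657,0.5067,-0.0333,-0.0891,0.4706,-0.0419
wealth[richest],wealth,-0.0915,0.8436,-0.0772,-0.0763,0.8394,-0.0641
head[female],household_head,-0.0152,-0.0077,0.0001,-0.0251,-0.0441,0.0011
marital[married],marital_status,0.0810,0.0014,0.0001,-0.4651,0.0008,-0.0004
residence[rural],residence,0.0280,-0.0645,-0.0018,0.0613,-0.1963,-0.0120
zone[hills],ecological_zone,0.0321,-0.1760,-0.0057,0.0093,-0.1308,-0.0012
zone[terai],ecological_zone,0.0679,0.1948,0.0132,0.1039,0.1657,0.0172
religion[buddhist],religion,0.0100,-0.1081,-0.0011,-0.0023,0.0084,0.0000
religion[muslim],religion,-0.0030,0.0931,-0.0003,0.0048,0.2085,0.0010
religion[kirat],religion,0.0016,-0.1261,-0.0002,0.0032,-0.0951,-0.0003
religion[christian],religion,0.0031,0.1537,0.0005,0.0046,-0.0087,0.0000
education[primary],education,-0.0465,-0.0889,0.0041,-0.0503,-0.1795,0.0090
education[secondary],education,-0.1122,0.3285,-0.0368,-0.1841,0.0807,-0.0149
education[higher],education,-0.0482,0.6928,-0.0334,-0.1652,0.4394,-0.0726
partner_education[educated],partner_education,-0.1511,0.0893,-0.0135,-0.1482,0.0418,-0.0062
occupation[working],occupation,-0.0368,-0.1265,0.0047,-0.1032,-0.1401,0.0145
distance[problem],distance,0.0507,-0.2057,-0.0104,0.0386,-0.1565,-0.0060
children,children,0.2848,-0.1215,-0.0346,0.3547,-0.0812,-0.0288
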