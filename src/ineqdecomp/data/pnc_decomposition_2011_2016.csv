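label,group,zeta_2011,ci_2011,contrib_2011,zeta_2016,ci_2016,contrib_2016
age[25-34],age,-0.0292,0.0554,-0.0016,-0.0066,0.0596,-0.0004
age[35-49],age,-0.0094,-0.3179,0.0030,-0.0028,-0.1541,0.0004
wealth[poorer],wealth,-0.0215,-0.3108,0.0067,-0.0123,-0.3787,0.0046
wealth[middle],wealth,-0.0471,0.1155,-0.0054,-0.0269,0.0482,-0.0013
wealth[richer],wealth,-0.0630,0.5062,-0.0319,-0.0382,0.4723,-0.0181
wealth[richest],wealth,-0.0652,0.8446,-0.0551,-0.0504,0.8364,-0.0422
head[female],household_head,-0.0076,-0.0075,0.0001,-0.0179,-0.0432,0.0008
marital[married],marital_status,0.0985,0.0014,0.0001,0.0993,0.0008,0.0001
residence[rural],residence,0.0384,-0.0645,-0.0025,0.0059,-0.1959,-0.0012
zone[hills],ecological_zone,0.0657,-0.1760,-0.0116,0.0492,-0.1321,-0.0065
zone[terai],ecological_zone,0.0931,0.1949,0.0181,0.1089,0.1667,0.0181
religion[buddhist],religion,0.0184,-0.1071,-0.0020,-0.0001,0.0092,0.0000
religion[muslim],religion,0.0003,0.0926,0.0000,0.0015,0.2103,0.0003
religion[kirat],religion,0.0026,-0.1267,-0.0003,-0.0010,-0.0943,0.0001
religion[christian],religion,0.0011,0.1535,0.0002,-0.0013,-0.0078,0.0000
education[primary],education,-0.0298,-0.0892,0.0027,0.0050,-0.1789,-0.0009
education[secondary],education,-0.0659,0.3281,-0.0216,-0.0109,0.0791,-0.0009
education[higher],education,-0.0297,0.6935,-0.0206,-0.0185,0.4413,-0.0082
partner_education[educated],partner_education,-0.1545,0.0892,-0.0138,0.0328,0.0417,0.0014
occupation[working],occupation,-0.0003,-0.1265,0.0000,-0.0534,-0.1406,0.0075
distance[problem],distance,0.0221,-0.2056,-0.0045,-0.0484,-0.1572,0.0076
children,children,0.1852,-0.1212,-0.0225,0.1044,-0.0813,-0.0085
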