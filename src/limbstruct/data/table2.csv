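taxon,specimen,date_myr,graph_no,F50Zp,H35Zp,FHDSI,TPLML,HDARTML,F80Zx,F80Zy
Australopithecus africanus,Stw 99,2.6,1,2499,,39.1,,,1755,2257
Australopithecus africanus,Stw 431,2.6,2,,1279,42.0,,41.3,,
Paranthropus boisei?,KNM-ER 739,1.5,3,,2217,,,45.6,,
Homo sp.,KNM-ER 1472,2.0,4,2395,,40.3,64.5,,1040,1794
Homo sp.,KNM-ER 1481,1.9,5,1918,,43.2,69.3,,1180,1800
Homo erectus,KNM-ER 1808,1.6,6,3216,884,,,,1603,2442
Homo erectus,KNM-WT 15000,1.5,7,1828,763,44.9,66.8,38.2,,
Homo erectus?,Gombore MK3,1.4,8,,1770,,,55.2,,
Homo antecessor,ATD6-148,0.9,9,,900,,,44.6,,
Homo heidelbergensis,Atap. SH-XV,0.6,10,,1041,,,45.0,,
Homo heidelbergensis,Atap. SH-III,0.6,11,,1510,,,47.9,,
Paranthropus robustus,SK 82,1.7,12,,,,,,1461,1911
Paranthropus robustus,SK 97,1.7,13,,,,,,1441,2023
Paranthropus boisei,KNM-ER 1500,1.9,14,,,,,,921,1095
Paranthropus boisei,OH 80,1.3,15,,,,,,1682,1965
Paranthropus boisei?,KNM-ER 993,1.5,16,,,,,,1617,2128
Paranthropus boisei?,KNM-ER 1463,1.4,17,,,,,,1053,1096
Paranthropus boisei?,KNM-ER 1503,1.9,18,,,,,,1266,1631
Paranthropus boisei?,KNM-ER 815,1.8,19,,,,,,737,1053
Paranthropus boisei?,KNM-ER 738,1.9,20,,,,,,1008,1323
Paranthropus boisei?,KNM-ER 1465,1.5,21,,,,,,1576,1980
Paranthropus boisei?,OH 20,1.7,22,,,,,,1329,1802
Homo erectus,KNM-ER 737,1.6,23,,,,,,1814,2905
Homo erectus,KNM-ER 803,1.5,24,,,,,,1897,2593
Homo erectus,Kresna 11,0.9,25,,,,,,1696,2487
Homo erectus,OH 28,0.7,26,,,,,,1521,2665
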