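# nominal_fps: 30.0
# participant: EXAMPLE
# condition: static
t,lm00_x,lm00_y,lm00_z,lm00_vis,lm01_x,lm01_y,lm01_z,lm01_vis,lm02_x,lm02_y,lm02_z,lm02_vis,lm03_x,lm03_y,lm03_z,lm03_vis,lm04_x,lm04_y,lm04_z,lm04_vis,lm05_x,lm05_y,lm05_z,lm05_vis,lm06_x,lm06_y,lm06_z,lm06_vis,lm07_x,lm07_y,lm07_z,lm07_vis,lm08_x,lm08_y,lm08_z,lm08_vis,lm09_x,lm09_y,lm09_z,lm09_vis,lm10_x,lm10_y,lm10_z,lm10_vis,lm11_x,lm11_y,lm11_z,lm11_vis,lm12_x,lm12_y,lm12_z,lm12_vis,lm13_x,lm13_y,lm13_z,lm13_vis,lm14_x,lm14_y,lm14_z,lm14_vis,lm15_x,lm15_y,lm15_z,lm15_vis,lm16_x,lm16_y,lm16_z,lm16_vis,lm17_x,lm17_y,lm17_z,lm17_vis,lm18_x,lm18_y,lm18_z,lm18_vis,lm19_x,lm19_y,lm19_z,lm19_vis,lm20_x,lm20_y,lm20_z,lm20_vis,lm21_x,lm21_y,lm21_z,lm21_vis,lm22_x,lm22_y,lm22_z,lm22_vis,lm23_x,lm23_y,lm23_z,lm23_vis,lm24_x,lm24_y,lm24_z,lm24_vis,lm25_x,lm25_y,lm25_z,lm25_vis,lm26_x,lm26_y,lm26_z,lm26_vis,lm27_x,lm27_y,lm27_z,lm27_vis,lm28_x,lm28_y,lm28_z,lm28_vis,lm29_x,lm29_y,lm29_z,lm29_vis,lm30_x,lm30_y,lm30_z,lm30_vis,lm31_x,lm31_y,lm31_z,lm31_vis,lm32_x,lm32_y,lm32_z,lm32_vis
0,0.00062865110546696647,1.6793394756835434,1.9032021132522163,1,-0.019475499414234803,1.6973216531341944,1.9118079752745474,1,-0.023479999774349312,1.7047354048156462,1.906481323820965,1,-0.046327107355230261,1.6968836276873132,1.9102066298967362,1,0.008374846126805828,1.6989060416803372,1.9037704452637345,1,0.026338663226482741,1.6972787050857134,1.9084184992181541,1,0.042058152681870666,1.7052125668472133,1.9093573266852797,1,-0.068167682647251565,1.6766740266325668,2.0017575503504652,1,0.079517350908259038,1.6804700614888044,1.996282503753231,1,-0.024608626881292096,1.6477113708716633,1.9111009756173503,1,0.014951909082306321,1.6489541221256414,1.9092038749504274,1,-0.19729577207657098,1.5010732956125317,2.0017768635451998,1,0.19673085695290832,1.4993519318315363,2.0039198773503069,1,-0.16268172856759652,1.1951935152764825,2.0075696188736951,1,0.17687826141261184,1.2053953999405054,2.0013222781516466,1,-0.098608322607604271,0.94886568736138344,2.0098012915822498,1,0.19935153607127795,0.93882063744866795,2.0017869020532948,1,-0.081418027397435755,0.86454197728008209,2.0032823746753818,1,0.1898851032708283,0.85444481061123745,2.0021493184741113,1,-0.081896220616210547,0.85864365811189658,1.9966914871398049,1,0.20414473435385999,0.846620190771463,2.0086968393856508,1,-0.09785598787823567,0.86620909609298358,1.9987071372726304,1,0.22424427498358668,0.85907100524573654,2.0031667631141246,1,-0.16101754940323326,1.0002601448712993,2.0034184309538827,1,0.15501980787921085,0.99691046477646195,2.0091100568166418,1,-0.15660215485006646,0.54669235989092391,2.0046752499405702,1,0.15024527306912655,0.5600119629182263,2.0009425959625622,1,-0.15316597045096114,0.098112182473835935,1.994544269411904,1,0.14361159916806696,0.10315205745384114,2.002905829062064,1,-0.14352720590279441,0.04622697104370032,2.0384455372622181,1,0.14856306146095666,0.05787204139422291,2.0278360707640868,1,-0.15367741646171137,0.051248926857793309,1.8851572654243474,1,0.15080504788357671,0.047072355879383292,1.8732939014296166,1
0.033333333333333333,-0.0070076010745871399,1.6825134142493743,1.9049485651664289,1,-0.020821472963126454,1.6946281757088577,1.9143652107631084,1,-0.036401969723572868,1.6964346595247035,1.9131050892677004,1,-0.051250705867872962,1.7019318479878316,1.9070917958179523,1,0.020546398487389071,1.6996214923688959,1.9110105719752197,1,0.03347085968353504,1.6962081512455078,1.9171049101115596,1,0.043630468944738827,1.7042186633115164,1.9158243199055551,1,-0.071062058891470645,1.684220393402893,2.0003779680537144,1,0.067866130745051337,1.6793247744998148,1.9961524267991164,1,-0.027113708842577067,1.6512922639545649,1.9071572527292617,1,0.014850977809942682,1.644784994599642,1.9113420853985446,1,-0.19820664025414828,1.5066122873488341,1.9999304266573796,1,0.20520919879606411,1.5070113241338625,2.0057508281807483,1,-0.18197540382508517,1.2076322615330204,2.001698100041243,1,0.17226774105796705,1.2033449800256846,2.0019137858013538,1,-0.095441637433660229,0.93978101740100561,1.9904918235081199,1,0.18979878808241021,0.92822645938239279,2.0054008170626894,1,-0.076820266766001788,0.86498162472621754,1.9957519702219493,1,0.19377379825008545,0.85241153500189437,1.9925731240786824,1,-0.083873008664551871,0.86403388667844383,1.9940714009749738,1,0.19433574626258723,0.85503446097972891,1.9985120798052833,1,-0.098026476302115695,0.86338347479641786,2.0090823797044055,1,0.21607790574427785,0.85290229662527006,1.9925646356516231,1,-0.14176330466821949,1.0045874399172214,2.005334674335026,1,0.15023836365605839,1.0045832739441229,2.0018547341754722,1,-0.14693405461070497,0.54923903520795858,1.9926305602597902,1,0.1551442717390159,0.54032520181695154,1.9988003166437098,1,-0.1510226124419983,0.09478569929507745,2.0030656156816828,1,0.14899835149295215,0.097815658372013572,2.0025992086548881,1,-0.15238289520279205,0.056944899874191518,2.0317572753809365,1,0.14762833506582779,0.040278675120072258,2.0234612340154943,1,-0.14456584607615819,0.049746979684443263,1.8785843746716022,1,0.15821625807121348,0.043586753779630484,1.8770717110007931,1
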