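{"nominal_fps": 30.0, "metadata": {"participant": "EXAMPLE", "condition": "static"}}
{"t": 0.0, "lm": [[0.0006286511054669665, 1.6793394756835434, 1.9032021132522163, 1.0], [-0.019475499414234803, 1.6973216531341944, 1.9118079752745474, 1.0], [-0.023479999774349312, 1.7047354048156462, 1.906481323820965, 1.0], [-0.04632710735523026, 1.6968836276873132, 1.9102066298967362, 1.0], [0.008374846126805828, 1.6989060416803372, 1.9037704452637345, 1.0], [0.02633866322648274, 1.6972787050857134, 1.908418499218154, 1.0], [0.042058152681870666, 1.7052125668472133, 1.9093573266852797, 1.0], [-0.06816768264725157, 1.6766740266325668, 2.001757550350465, 1.0], [0.07951735090825904, 1.6804700614888044, 1.996282503753231, 1.0], [-0.024608626881292096, 1.6477113708716633, 1.9111009756173503, 1.0], [0.01495190908230632, 1.6489541221256414, 1.9092038749504274, 1.0], [-0.19729577207657098, 1.5010732956125317, 2.0017768635452, 1.0], [0.19673085695290832, 1.4993519318315363, 2.003919877350307, 1.0], [-0.16268172856759652, 1.1951935152764825, 2.007569618873695, 1.0], [0.17687826141261184, 1.2053953999405054, 2.0013222781516466, 1.0], [-0.09860832260760427, 0.9488656873613834, 2.00980129158225, 1.0], [0.19935153607127795, 0.938820637448668, 2.001786902053295, 1.0], [-0.08141802739743575, 0.8645419772800821, 2.003282374675382, 1.0], [0.1898851032708283, 0.8544448106112374, 2.0021493184741113, 1.0], [-0.08189622061621055, 0.8586436581118966, 1.996691487139805, 1.0], [0.20414473435386, 0.846620190771463, 2.008696839385651, 1.0], [-0.09785598787823567, 0.8662090960929836, 1.9987071372726304, 1.0], [0.22424427498358668, 0.8590710052457365, 2.0031667631141246, 1.0], [-0.16101754940323326, 1.0002601448712993, 2.0034184309538827, 1.0], [0.15501980787921085, 0.996910464776462, 2.009110056816642, 1.0], [-0.15660215485006646, 0.5466923598909239, 2.0046752499405702, 1.0], [0.15024527306912655, 0.5600119629182263, 2.000942595962562, 1.0], [-0.15316597045096114, 0.09811218247383593, 1.994544269411904, 1.0], [0.14361159916806696, 0.10315205745384114, 2.002905829062064, 1.0], [-0.1435272059027944, 0.04622697104370032, 2.038445537262218, 1.0], [0.14856306146095666, 0.05787204139422291, 2.027836070764087, 1.0], [-0.15367741646171137, 0.05124892685779331, 1.8851572654243474, 1.0], [0.1508050478835767, 0.04707235587938329, 1.8732939014296166, 1.0]]}
{"t": 0.03333333333333333, "lm": [[-0.00700760107458714, 1.6825134142493743, 1.9049485651664289, 1.0], [-0.020821472963126454, 1.6946281757088577, 1.9143652107631084, 1.0], [-0.03640196972357287, 1.6964346595247035, 1.9131050892677004, 1.0], [-0.05125070586787296, 1.7019318479878316, 1.9070917958179523, 1.0], [0.02054639848738907, 1.699621492368896, 1.9110105719752197, 1.0], [0.03347085968353504, 1.6962081512455078, 1.9171049101115596, 1.0], [0.04363046894473883, 1.7042186633115164, 1.9158243199055551, 1.0], [-0.07106205889147064, 1.684220393402893, 2.0003779680537144, 1.0], [0.06786613074505134, 1.6793247744998148, 1.9961524267991164, 1.0], [-0.027113708842577067, 1.6512922639545649, 1.9071572527292617, 1.0], [0.014850977809942682, 1.644784994599642, 1.9113420853985446, 1.0], [-0.19820664025414828, 1.5066122873488341, 1.9999304266573796, 1.0], [0.2052091987960641, 1.5070113241338625, 2.0057508281807483, 1.0], [-0.18197540382508517, 1.2076322615330204, 2.001698100041243, 1.0], [0.17226774105796705, 1.2033449800256846, 2.001913785801354, 1.0], [-0.09544163743366023, 0.9397810174010056, 1.99049182350812, 1.0], [0.1897987880824102, 0.9282264593823928, 2.0054008170626894, 1.0], [-0.07682026676600179, 0.8649816247262175, 1.9957519702219493, 1.0], [0.19377379825008545, 0.8524115350018944, 1.9925731240786824, 1.0], [-0.08387300866455187, 0.8640338866784438, 1.9940714009749738, 1.0], [0.19433574626258723, 0.8550344609797289, 1.9985120798052833, 1.0], [-0.0980264763021157, 0.8633834747964179, 2.0090823797044055, 1.0], [0.21607790574427785, 0.8529022966252701, 1.9925646356516231, 1.0], [-0.1417633046682195, 1.0045874399172214, 2.005334674335026, 1.0], [0.1502383636560584, 1.004583273944123, 2.001854734175472, 1.0], [-0.14693405461070497, 0.5492390352079586, 1.9926305602597902, 1.0], [0.1551442717390159, 0.5403252018169515, 1.9988003166437098, 1.0], [-0.1510226124419983, 0.09478569929507745, 2.003065615681683, 1.0], [0.14899835149295215, 0.09781565837201357, 2.002599208654888, 1.0], [-0.15238289520279205, 0.05694489987419152, 2.0317572753809365, 1.0], [0.1476283350658278, 0.04027867512007226, 2.0234612340154943, 1.0], [-0.1445658460761582, 0.04974697968444326, 1.8785843746716022, 1.0], [0.15821625807121348, 0.043586753779630484, 1.877071711000793, 1.0]]}
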