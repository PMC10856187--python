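compound_id,class,solvent,C1,C2,C3,C4,C5,C6,C7,C9,H_CHO_1,H_CHO_2,H_OH_1,H_OH_2
pyrano-diformyl-000,pyrano-diformyl,CDCl3,166.44369095469813,104.73595567017703,168.8533817897262,105.81931469005711,166.21756731806389,103.26088694178098,191.28453700138962,192.31366954049778,10.616347724744115,10.838354018695966,13.474703662980577,14.825922252159808
pyrano-diformyl-001,pyrano-diformyl,CDCl3,163.8141103423779,103.8804528158698,168.25891836579058,105.4810112563504,165.4384358733887,104.70171513694939,191.47967639902427,191.57844480009342,9.995270675239157,,12.203027338909617,
pyrano-diformyl-002,pyrano-diformyl,CDCl3,164.53936358055591,103.1722664476688,167.91840802753092,105.28913298762518,165.1855310342101,106.12066650964927,192.39670790407982,191.88814071981128,9.608504150265977,9.33553199447206,12.395973355589767,
pyrano-diformyl-003,pyrano-diformyl,CDCl3,163.83616042943828,102.91407541789691,166.2638551914259,107.10344689820855,166.0282689230974,104.52463416022627,190.66495010043238,190.25411776193488,11.347155852657243,9.389766199231229,13.782757699862474,13.384778681359098
oxepine-diformyl-000,oxepine-diformyl,CDCl3,165.04865202947812,99.20460808376717,166.56334733336266,105.21197212635535,167.3227622761056,107.16970036320379,195.37356057620528,189.28704354107316,10.125275823650227,,11.616626196620643,14.078890154664263
oxepine-diformyl-001,oxepine-diformyl,CDCl3,164.54676971035266,100.66688638908013,168.71975423450988,106.26036492501974,165.16732420697295,106.3104617185416,196.13279264112066,191.64412225011213,10.627417309466562,9.56383744346683,14.194394261606678,13.237710280624745
oxepine-diformyl-002,oxepine-diformyl,CDCl3,164.49510108932395,99.51840023519796,167.46771646575857,104.40395757994666,163.99504731296284,107.58017004315396,197.66962786569744,191.1054460741334,9.513500697748032,,12.711966636370926,13.966183112801048
oxepine-diformyl-003,oxepine-diformyl,CDCl3,163.37899950708942,100.86434174959784,168.3016569568321,105.38716170337304,166.92768755865518,109.02051925548542,194.97251678957906,191.85205260843554,10.112216728069713,9.471517998737221,11.924846786321933,14.196027112745206
euglobal-type-000,euglobal-type,CDCl3,164.69922301269992,96.61504609046146,169.1538036327254,105.43290486159428,165.89451906057454,111.73020332067225,200.33071677669275,191.15734237877837,8.742252199283495,10.239545910392748,12.632632113568777,
euglobal-type-001,euglobal-type,CDCl3,164.81579239613876,96.38232312588842,167.8595330206155,102.92421256985754,166.5018157297761,111.07891251643693,200.59840401025784,188.66710184830862,10.860696902730234,,14.012181946697758,13.642163074903973
euglobal-type-002,euglobal-type,CDCl3,166.53388034406404,95.77177613914179,168.41936078258433,106.57766682042603,166.3425211107702,113.4223045163746,200.5776949063579,191.16262144644017,10.056478407206,9.96775432626105,12.447248770485547,13.953048256701653
euglobal-type-003,euglobal-type,CDCl3,165.5147759063718,97.00171452352373,168.3481059464043,104.25486131534467,166.86330125756464,110.17628892873508,199.66392926311752,192.29309084421885,10.951876490210982,10.9963590461082,9.757072466818023,
pyrano-3-acyl-1-formyl-000,pyrano-3-acyl-1-formyl,CDCl3,163.65135425283881,103.67425077493537,168.4286110525435,110.14480366542915,165.22539508331985,104.65745706037129,191.8465988390819,187.3820595839077,11.352499781890147,,13.755879685936296,
pyrano-3-acyl-1-formyl-001,pyrano-3-acyl-1-formyl,CDCl3,164.13061806008704,102.6154698853234,167.70600919016937,108.98117414098216,165.2344014116849,104.31572273821662,193.1821206652973,186.46379279908405,11.586690122336,10.410747061298762,11.804866613383682,13.60489374358312
pyrano-3-acyl-1-formyl-002,pyrano-3-acyl-1-formyl,CDCl3,165.6293573583143,105.39376632211975,166.4509648612499,108.4654063362181,166.43995295272993,102.70078956252708,193.87690374848353,186.98076475780405,11.377097187500002,9.265220277248732,12.24218210224642,
pyrano-3-acyl-1-formyl-003,pyrano-3-acyl-1-formyl,CDCl3,163.42854355638244,104.01171182678415,168.6511591416878,111.28971137337876,165.95700668909893,102.37541868389852,192.40951470318257,187.32856245535368,9.756810527169298,10.275324354124995,13.298125013386324,12.644166733703544
oxepine-1-formyl-3-acyl-000,oxepine-1-formyl-3-acyl,CDCl3,165.5954869020015,98.90972395424227,168.3951192601444,106.94786956895683,166.05667478459202,106.48048297117006,194.62030839263443,187.79255375643336,7.830918799895926,11.01387033941109,12.701785578850288,13.30314737906681
oxepine-1-formyl-3-acyl-001,oxepine-1-formyl-3-acyl,CDCl3,166.20567584005852,101.00469389163305,167.45591042132327,108.94952405742178,165.69421297172124,106.6075919838191,196.4749009125181,187.1819453233678,9.35175022672977,8.730696587919622,11.358087955886411,
oxepine-1-formyl-3-acyl-002,oxepine-1-formyl-3-acyl,CDCl3,165.55725400053672,99.97437460583747,168.60278853526674,109.28283868011826,165.9045030615077,107.22147049666052,195.88133870028753,187.09976756213757,9.508992850901,11.215733165639548,11.91678785742949,12.473928131922165
oxepine-1-formyl-3-acyl-003,oxepine-1-formyl-3-acyl,CDCl3,165.95425852130722,101.37712394811717,167.98217600776022,107.61507993835731,166.49937206119677,108.90708248258449,197.05108002481387,186.64526026274518,10.044632728936978,,13.169240471551474,
macrocarpal-type-000,macrocarpal-type,CDCl3,165.18097774249637,96.22762526343172,168.95647153612632,108.3716833899592,165.63877343423158,112.11778517456624,200.27036735875163,188.3958139257651,8.705342675037656,10.298507268563522,12.192760263527516,12.665197514249778
macrocarpal-type-001,macrocarpal-type,CDCl3,165.13655749157596,95.51941866104065,167.54909344886715,107.15545005480911,166.12658483208935,111.46563068326566,199.0744154204247,186.7349905651325,9.585308785394234,10.232494360233542,12.115417649730848,
macrocarpal-type-002,macrocarpal-type,CDCl3,166.14029901052984,93.93282889739011,168.599729852336,108.87605611566492,166.5981970069908,110.49658812834559,199.9447153944663,187.34065041999852,9.405497449382622,8.738254531883266,13.865725918926396,14.062081992215735
macrocarpal-type-003,macrocarpal-type,CDCl3,166.07119421509452,96.26954771658681,166.41108320897982,109.68559847699407,165.19390823959003,113.23737015145032,200.59050818114528,185.98050439732,8.775240369596608,,11.861912436089382,14.50491314122754
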