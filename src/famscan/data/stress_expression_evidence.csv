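record_id,genes,source_id,condition
BN11150,BnaWRKY048;BnaWRKY240,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN11784,BnaWRKY042;BnaWRKY245;BnaWRKY235,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN12248,BnaWRKY028;BnaWRKY125;BnaWRKY265,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN14657,BnaWRKY059;BnaWRKY202;BnaWRKY166,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN14658,BnaWRKY072;BnaWRKY194,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN14659,BnaWRKY194,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN14671,BnaWRKY113;BnaWRKY261,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN15417,BnaWRKY005;BnaWRKY145,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN17285,BnaWRKY169;BnaWRKY191;BnaWRKY033,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN18870,BnaWRKY083,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN19742,BnaWRKY009;BnaWRKY141,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN19744,BnaWRKY049;BnaWRKY098;BnaWRKY241,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN19745,BnaWRKY098;BnaWRKY182,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN20043,BnaWRKY001,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN20181,BnaWRKY055,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN20309,BnaWRKY040,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN22940,BnaWRKY100;BnaWRKY247,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN23484,BnaWRKY143,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN23912,BnaWRKY095;BnaWRKY225,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN24283,BnaWRKY061,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN24410,BnaWRKY094;BnaWRKY224,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN24459,BnaWRKY126;BnaWRKY127;BnaWRKY210,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN25151,BnaWRKY007;BnaWRKY147,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN25335,BnaWRKY064;BnaWRKY035;BnaWRKY204;BnaWRKY189;BnaWRKY171,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN25509,BnaWRKY118;BnaWRKY249,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN25589,BnaWRKY082;BnaWRKY232,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN26453,BnaWRKY050;BnaWRKY111;BnaWRKY195;BnaWRKY259,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN26664,BnaWRKY079;BnaWRKY178,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
BN27460,BnaWRKY048,GSM334324-GSM334353 GSM334645-GSM334674,Sclerotinia sclerotiorum
EV194691.1,BnaWRKY125;BnaWRKY265,dbEST 21489,cold stress
EV218409.1,BnaWRKY242,dbEST 21492,drought stress
BG543395.1,BnaWRKY033;BnaWRKY169,dbEST 8791,Etiolated seedling
BG543470.1,BnaWRKY033;BnaWRKY169,dbEST 8791,Etiolated seedling
EV113703.1,BnaWRKY118;BnaWRKY249,dbEST 21479,hydroponically grown root
EV113780.1,BnaWRKY118;BnaWRKY249,dbEST 21479,hydroponically grown root
EV113862.1,BnaWRKY118;BnaWRKY249,dbEST 21479,hydroponically grown root
EV113948.1,BnaWRKY118;BnaWRKY249,dbEST 21479,hydroponically grown root
EV116356.1,BnaWRKY005;BnaWRKY145,dbEST 21479,hydroponically grown root
EV116444.1,BnaWRKY005;BnaWRKY145,dbEST 21479,hydroponically grown root
EV117836.1,BnaWRKY141;BnaWRKY009,dbEST 21479,hydroponically grown root
EV179662.1,BnaWRKY055,dbEST 21487,Etiolated seedlings
EV179750.1,BnaWRKY055,dbEST 21487,Etiolated seedlings
EV181284.1,BnaWRKY141;BnaWRKY009,dbEST 21487,Etiolated seedlings
EV181367.1,BnaWRKY141;BnaWRKY009,dbEST 21487,Etiolated seedlings
EV186271.1,BnaWRKY199;BnaWRKY058,dbEST 21488,infestation by flea beetles
EV194778.1,BnaWRKY125;BnaWRKY265,dbEST 21489,cold stress
EV220289.1,BnaWRKY141;BnaWRKY009,dbEST 21492,drought stress
EV220578.1,BnaWRKY141;BnaWRKY009,dbEST 21492,drought stress
EV223313.1,BnaWRKY005;BnaWRKY145,dbEST 21493,insect damage
EV225488.1,BnaWRKY005;BnaWRKY145,dbEST 21493,insect damage
EX019274.1,BnaWRKY062,dbEST 21809,cold stress
EX062868.1,BnaWRKY191,dbEST 21814,etiolated mature leaf dark grown
EX063926.1,BnaWRKY242,dbEST 21814,etiolated mature leaf dark grown
EX064286.1,BnaWRKY062,dbEST 21814,etiolated mature leaf dark grown
EX097528.1,BnaWRKY033;BnaWRKY169,dbEST 21824,disease
EX120320.1,BnaWRKY062,dbEST 21829,defected leaf
EX125680.1,BnaWRKY191,dbEST 21831,etiolated mature leaf dark grown
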