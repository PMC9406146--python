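name	sequence	n_term	c_term	concentration_mM
CysZ1	ARKQIV	free	amide	4.210
CysZ2	RKQIVA	free	amide	4.210
CysZ3	KQIVAG	free	amide	4.888
CysZ4	QIVAGV	free	amide	2.565
CysZ5	IVAGVN	free	free-acid	5.257
CysZ8	GVNYFL	free	amide	2.110
CysZ13	QAGIVV	free	amide	1.710
CysZ14	QIGVAV	free	amide	1.710
QIVFFA	QIVFFA	free	amide	1.384
TauR2wt	VQIINK	free	amide	5.784
TauR3-P312	VQIVYK	free	amide	1.337
Sup35_7-13	GNNQQNY	free	amide	1.196
KGHK-KGHK	KGHKGGGAAPVGGGKGHK	acetyl	amide	0.609
IM-IM	RDKVYRGGGAAPVGGGRDKVYR	acetyl	amide	0.421
FC-GHK	GHKGGGAAPVGGGQAGIVV	acetyl	amide	0.614
FC-KGHK	KGHKGGGAAPVGGGQAGIVV	acetyl	amide	0.569
FC-IM	RDKVYRGGGAAPVGGGQAGIVV	acetyl	amide	0.470
RADA-IM	RADARADARADARADAGGGAAPVGGGRDKVYR	acetyl	amide	3.116
RADA-GHK	RADARADARADARADAGGGAAPVGGGHK	acetyl	amide	3.763
RADA-KGHK	RADARADARADARADAGGGAAPVGGGKGHK	acetyl	amide	3.518
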