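accession_name	taxon	ploidy	its_lengths	heterozygosity_pct	its_accessions	clone_number	trnLF_bp	trnLF_accession	trnTL_bp	trnTL_accession
Agentingsang	M. alba	4x	611/624	40	MN044824/MN044849	20	921	MN057958	1096	MN057991
Banqiao6	M. alba	4x	611	0	MN044817	7	921	MN057959	1078	MN057992
Basailuona	M. alba	4x	611	0	MN044831	7	921	MN057961	1078	MN057994
Gailiang10	M. alba	4x	611	0	MN044828	7	921	MN057975	1089	MN057808
Hanguodabaizhenzhu	M. alba	4x	611/611	14.29	MN044825/MN044851	7	921	MN057965	1118	MN057998
Huasang	M. alba	4x	611	0	MN044813	7	921	MN057967	1078	MN057800
Huai302	M. alba	12x	611	0	MN044836	7	921	MN057966	1078	MN057999
Huosang	M. alba	4x	611/624	5.26	MN044833/MN044850	19	921	MN057968	1078	MN057801
Jianpuzhai	M. alba	6x	611/625	10	MN044834/MN044854	10	921	MN057969	1112	MN057802
Leshandahongpi	M. alba	6x	611	0	MN044823	7	921	MN057971	1111	MN057804
Lunjiao109	M. alba	4x	611/624	25	MN044822/MN044847	16	921	MN057972	1118	MN057805
Shanxitiansang	M. alba	4x	611/624	5	MN044832/MN044846	20	921	MN057976	1079	MN057809
Shimiansang	M. alba	4x	611/611	14.29	MN044818/MN044845	7	922	MN057977	1079	MN057810
Shuisang	M. alba	4x	611/611	14.29	MN044821/MN044835	7	921	MN057978	1117	MN057811
Sililanka	M. alba	4x	611	0	MN044830	7	921	MN057980	1078	MN057813
Taiwanchaochangguo	M. alba	4x	611	0	MN044820	7	921	MN057981	1119	MN057814
Wupisang	M. alba	4x	611	0	MN044814	7	922	MN057982	1078	MN057815
Xinjiaposijiguosang	M. alba	4x	611	0	MN044827	7	921	MN057979	1118	MN057812
Xinyizhilai	M. alba	4x	611/624	20	MN044829/MN044848	20	921	MN057983	1078	MN057816
Yidachimu	M. alba	4x	611	0	MN044826	7	921	MN057985	1077	MN057818
Zhenzhubai	M. alba	4x	611	0	MN044819	7	922	MN057988	1118	MN057821
Baojing7	M. cathayana	12x	611/626	5	MN044838/MN044852	20	922	MN057960	1112	MN057993
Gui23	M. cathayana	12x	611	0	MN044837	7	921	MN057964	1112	MN057997
Pisang2	M. cathayana	18x	611/611	14.29	MN044839/MN044844	7	921	MN057974	1112	MN057807
Jimengsang	M. mongolica	4x	611	0	MN044815	7	921	MN057970	1078	MN057803
Mengsang	M. mongolica	4x	611	0	MN044816	7	922	MN057973	1078	MN057806
M. nigra	M. nigra	44x	624	0	KF784875	7	922	MN057984	1105	MN057817
M. notabilis	M. notabilis	2x	631	0	KF784877	7	918	MN057962	1092	MN057995
Yun6	M. wittiorum	5x	611/625	45	MN044840/MN044856	20	921	MN057986	1112	MN057819
Yun6muben	M. wittiorum	4x	625/624	14.29	MN044855/MN044843	7	921	MN057989	1112	MN057822
Yun7	M. wittiorum	7x	611/626	5	MN044842/MN044853	20	921	MN057987	1098	MN057820
Yun7muben	M. wittiorum	8x	611	0	MN044841	7	921	MN057990	1098	MN057823
M. yunnanensis	M. yunnanensis	2x	631	0	KF850474	7	918	MN057963	1094	MN057996
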