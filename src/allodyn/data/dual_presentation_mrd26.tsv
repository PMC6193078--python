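gene	hla_class	peptide	allele	ic50
AGXT2	I	FAVEVFRSA	HLA-A*02:01	1516.1
AGXT2	I	FAVEVFRSA	HLA-A*30:02	19896.3
AGXT2	I	FAVEVFRSA	HLA-B*18:01	12500.5
AGXT2	I	FAVEVFRSA	HLA-B*55:01	1455.5
AGXT2	I	FAVEVFRSA	HLA-C*03:03	40.2
AGXT2	I	FAVEVFRSA	HLA-C*05:01	10055.5
AGXT2	II	FAVEVFRSALTQHME	HLA-DRB1*03:01	460.1
AGXT2	II	FAVEVFRSALTQHME	HLA-DRB1*04:01	28.9
AK9	I	FLMNPRPYL	HLA-A*02:01	4.3
AK9	I	FLMNPRPYL	HLA-A*30:02	4760.2
AK9	I	FLMNPRPYL	HLA-B*18:01	20565.6
AK9	I	FLMNPRPYL	HLA-B*55:01	7448.6
AK9	I	FLMNPRPYL	HLA-C*03:03	25.3
AK9	I	FLMNPRPYL	HLA-C*05:01	1336.9
AK9	II	ALKPFLMNPRPYLLP	HLA-DRB1*03:01	29.3
AK9	II	ALKPFLMNPRPYLLP	HLA-DRB1*04:01	193.0
ASPM	I	ASIVIQSTY	HLA-A*02:01	31629.4
ASPM	I	ASIVIQSTY	HLA-A*30:02	44.2
ASPM	I	ASIVIQSTY	HLA-B*18:01	13973.2
ASPM	I	ASIVIQSTY	HLA-B*55:01	18924.6
ASPM	I	ASIVIQSTY	HLA-C*03:03	4613.3
ASPM	I	ASIVIQSTY	HLA-C*05:01	10787.6
ASPM	II	HKASIVIQSTYRMYR	HLA-DRB1*03:01	25.7
ASPM	II	HKASIVIQSTYRMYR	HLA-DRB1*04:01	60.0
AVPR1A	I	FGMFPSAYM	HLA-A*02:01	3674.0
AVPR1A	I	FGMFPSAYM	HLA-A*30:02	3498.8
AVPR1A	I	FGMFPSAYM	HLA-B*18:01	12767.8
AVPR1A	I	FGMFPSAYM	HLA-B*55:01	7866.3
AVPR1A	I	FGMFPSAYM	HLA-C*03:03	11.4
AVPR1A	I	FGMFPSAYM	HLA-C*05:01	2197.5
AVPR1A	II	HLQVFGMFPSAYMLV	HLA-DRB1*03:01	2331.0
AVPR1A	II	HLQVFGMFPSAYMLV	HLA-DRB1*04:01	43.9
CATSPERD	I	YSLTAQSAM	HLA-A*02:01	10576.8
CATSPERD	I	YSLTAQSAM	HLA-A*30:02	4156.0
CATSPERD	I	YSLTAQSAM	HLA-B*18:01	12288.7
CATSPERD	I	YSLTAQSAM	HLA-B*55:01	8996.0
CATSPERD	I	YSLTAQSAM	HLA-C*03:03	8.7
CATSPERD	I	YSLTAQSAM	HLA-C*05:01	1407.0
CATSPERD	II	SYSYSLTAQSAMCTS	HLA-DRB1*03:01	2896.8
CATSPERD	II	SYSYSLTAQSAMCTS	HLA-DRB1*04:01	41.7
MC1R	I	ISIFYALRY	HLA-A*02:01	25706.3
MC1R	I	ISIFYALRY	HLA-A*30:02	31.9
MC1R	I	ISIFYALRY	HLA-B*18:01	8957.9
MC1R	I	ISIFYALRY	HLA-B*55:01	19531.2
MC1R	I	ISIFYALRY	HLA-C*03:03	5801.1
MC1R	I	ISIFYALRY	HLA-C*05:01	9626.4
MC1R	II	YALRYHSIVTLPRAR	HLA-DRB1*03:01	135.3
MC1R	II	YALRYHSIVTLPRAR	HLA-DRB1*04:01	18.1
NOP56	I	KTRGNTPKY	HLA-A*02:01	35107.0
NOP56	I	KTRGNTPKY	HLA-A*30:02	15.5
NOP56	I	KTRGNTPKY	HLA-B*18:01	27598.1
NOP56	I	KTRGNTPKY	HLA-B*55:01	14424.7
NOP56	I	KTRGNTPKY	HLA-C*03:03	9963.6
NOP56	I	KTRGNTPKY	HLA-C*05:01	22714.2
NOP56	II	KALFRALKTRGNTPK	HLA-DRB1*03:01	994.0
NOP56	II	KALFRALKTRGNTPK	HLA-DRB1*04:01	41.2
OR1I1	I	QLLDVYHVL	HLA-A*02:01	11.6
OR1I1	I	QLLDVYHVL	HLA-A*30:02	8139.2
OR1I1	I	QLLDVYHVL	HLA-B*18:01	14953.2
OR1I1	I	QLLDVYHVL	HLA-B*55:01	30075.2
OR1I1	I	QLLDVYHVL	HLA-C*03:03	755.1
OR1I1	I	QLLDVYHVL	HLA-C*05:01	11126.0
OR1I1	II	LDVYHVLGSLLAARD	HLA-DRB1*03:01	846.9
OR1I1	II	LDVYHVLGSLLAARD	HLA-DRB1*04:01	47.0
OR4C3	I	TAPAFSVTL	HLA-A*02:01	5503.3
OR4C3	I	TAPAFSVTL	HLA-A*30:02	20654.6
OR4C3	I	TAPAFSVTL	HLA-B*18:01	22712.2
OR4C3	I	TAPAFSVTL	HLA-B*55:01	25030.0
OR4C3	I	TAPAFSVTL	HLA-C*03:03	43.7
OR4C3	I	TAPAFSVTL	HLA-C*05:01	1962.4
OR4C3	II	LLVFIGNTAPAFSVT	HLA-DRB1*03:01	462.0
OR4C3	II	LLVFIGNTAPAFSVT	HLA-DRB1*04:01	40.8
OR2T8	I	LLIHWDHRL	HLA-A*02:01	20.0
OR2T8	I	LLIHWDHRL	HLA-A*30:02	10956.6
OR2T8	I	LLIHWDHRL	HLA-B*18:01	27156.7
OR2T8	I	LLIHWDHRL	HLA-B*55:01	27657.6
OR2T8	I	LLIHWDHRL	HLA-C*03:03	1524.5
OR2T8	I	LLIHWDHRL	HLA-C*05:01	8839.8
OR2T8	II	LIHWDHRLHTPMYFL	HLA-DRB1*03:01	36.4
OR2T8	II	LIHWDHRLHTPMYFL	HLA-DRB1*04:01	842.3
DENND3	I	FVMAPTSFL	HLA-A*02:01	10.3
DENND3	I	FVMAPTSFL	HLA-A*30:02	3652.5
DENND3	I	FVMAPTSFL	HLA-B*18:01	17042.6
DENND3	I	FVMAPTSFL	HLA-B*55:01	2484.8
DENND3	I	FVMAPTSFL	HLA-C*03:03	4.5
DENND3	I	FVMAPTSFL	HLA-C*05:01	389.9
DENND3	II	MLDFVMAPTSFLMGC	HLA-DRB1*03:01	238.6
DENND3	II	MLDFVMAPTSFLMGC	HLA-DRB1*04:01	17.4
FAM186A	I	HMDTVQLGY	HLA-A*02:01	11356.2
FAM186A	I	HMDTVQLGY	HLA-A*30:02	49.5
FAM186A	I	HMDTVQLGY	HLA-B*18:01	6536.0
FAM186A	I	HMDTVQLGY	HLA-B*55:01	21226.9
FAM186A	I	HMDTVQLGY	HLA-C*03:03	9349.7
FAM186A	I	HMDTVQLGY	HLA-C*05:01	1234.1
FAM186A	II	EILHMDTVQLGYLFR	HLA-DRB1*03:01	46.0
FAM186A	II	EILHMDTVQLGYLFR	HLA-DRB1*04:01	109.9
KRT19	I	VSSSSSGAY	HLA-A*02:01	35731.6
KRT19	I	VSSSSSGAY	HLA-A*30:02	24.1
KRT19	I	VSSSSSGAY	HLA-B*18:01	14800.9
KRT19	I	VSSSSSGAY	HLA-B*55:01	14059.5
KRT19	I	VSSSSSGAY	HLA-C*03:03	2267.3
KRT19	I	VSSSSSGAY	HLA-C*05:01	3801.6
KRT19	II	ARFVSSSSSGAYGGG	HLA-DRB1*03:01	3454.2
KRT19	II	ARFVSSSSSGAYGGG	HLA-DRB1*04:01	27.7
OTOF	I	MSNNKRVAY	HLA-A*02:01	30323.2
OTOF	I	MSNNKRVAY	HLA-A*30:02	41.0
OTOF	I	MSNNKRVAY	HLA-B*18:01	4779.4
OTOF	I	MSNNKRVAY	HLA-B*55:01	6417.7
OTOF	I	MSNNKRVAY	HLA-C*03:03	1125.4
OTOF	I	MSNNKRVAY	HLA-C*05:01	7254.6
OTOF	II	FIWMMSNNKRVAYAR	HLA-DRB1*03:01	71.8
OTOF	II	FIWMMSNNKRVAYAR	HLA-DRB1*04:01	37.8
TUBA3E	I	LMYAKSAFV	HLA-A*02:01	5.0
TUBA3E	I	LMYAKSAFV	HLA-A*30:02	2233.4
TUBA3E	I	LMYAKSAFV	HLA-B*18:01	26897.4
TUBA3E	I	LMYAKSAFV	HLA-B*55:01	10045.0
TUBA3E	I	LMYAKSAFV	HLA-C*03:03	1579.9
TUBA3E	I	LMYAKSAFV	HLA-C*05:01	6248.2
TUBA3E	II	KFDLMYAKSAFVHWY	HLA-DRB1*03:01	287.6
TUBA3E	II	KFDLMYAKSAFVHWY	HLA-DRB1*04:01	40.3
EXOC4	I	FLNMVCEKL	HLA-A*02:01	33.8
EXOC4	I	FLNMVCEKL	HLA-A*30:02	17747.3
EXOC4	I	FLNMVCEKL	HLA-B*18:01	28320.8
EXOC4	I	FLNMVCEKL	HLA-B*55:01	34391.9
EXOC4	I	FLNMVCEKL	HLA-C*03:03	2684.4
EXOC4	I	FLNMVCEKL	HLA-C*05:01	4867.5
EXOC4	II	ELEYIHALTLLHRSQ	HLA-DRB1*03:01	42.4
EXOC4	II	ELEYIHALTLLHRSQ	HLA-DRB1*04:01	19.3
MAGEL2	I	MVKVIHREY	HLA-A*02:01	30350.7
MAGEL2	I	MVKVIHREY	HLA-A*30:02	45.0
MAGEL2	I	MVKVIHREY	HLA-B*18:01	4482.6
MAGEL2	I	MVKVIHREY	HLA-B*55:01	8535.1
MAGEL2	I	MVKVIHREY	HLA-C*03:03	6459.2
MAGEL2	I	MVKVIHREY	HLA-C*05:01	30155.9
MAGEL2	II	APAVIRQAPPVIRQA	HLA-DRB1*03:01	28.1
MAGEL2	II	APAVIRQAPPVIRQA	HLA-DRB1*04:01	116.4
MUC16	I	TETEAIHVF	HLA-A*02:01	31916.8
MUC16	I	TETEAIHVF	HLA-A*30:02	18682.9
MUC16	I	TETEAIHVF	HLA-B*18:01	7.6
MUC16	I	TETEAIHVF	HLA-B*55:01	34699.1
MUC16	I	TETEAIHVF	HLA-C*03:03	19947.8
MUC16	I	TETEAIHVF	HLA-C*05:01	23268.2
MUC16	II	TSQGTFTLDSSSTAS	HLA-DRB1*03:01	408.1
MUC16	II	TSQGTFTLDSSSTAS	HLA-DRB1*04:01	45.4
TMPRSS9	I	FLSTQVFHV	HLA-A*02:01	2.7
TMPRSS9	I	FLSTQVFHV	HLA-A*30:02	12190.6
TMPRSS9	I	FLSTQVFHV	HLA-B*18:01	29318.2
TMPRSS9	I	FLSTQVFHV	HLA-B*55:01	19445.1
TMPRSS9	I	FLSTQVFHV	HLA-C*03:03	3194.4
TMPRSS9	I	FLSTQVFHV	HLA-C*05:01	2402.1
TMPRSS9	II	ELRGIRWTSSFRRET	HLA-DRB1*03:01	15.0
TMPRSS9	II	ELRGIRWTSSFRRET	HLA-DRB1*04:01	244.6
ZNF568	I	FSYDTQLSL	HLA-A*02:01	353.6
ZNF568	I	FSYDTQLSL	HLA-A*30:02	7765.1
ZNF568	I	FSYDTQLSL	HLA-B*18:01	17478.8
ZNF568	I	FSYDTQLSL	HLA-B*55:01	5206.5
ZNF568	I	FSYDTQLSL	HLA-C*03:03	3.8
ZNF568	I	FSYDTQLSL	HLA-C*05:01	150.4
ZNF568	II	GKAFSQSSSLTVHLR	HLA-DRB1*03:01	450.8
ZNF568	II	GKAFSQSSSLTVHLR	HLA-DRB1*04:01	33.1
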