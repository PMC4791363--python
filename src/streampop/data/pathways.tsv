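pathway	gene
cobalamin_synthesis	cysG
cobalamin_synthesis	cobA
cobalamin_synthesis	cobI
cobalamin_synthesis	cobG
cobalamin_synthesis	cobJ
cobalamin_synthesis	cobM
cobalamin_synthesis	cobF
cobalamin_synthesis	cobK
cobalamin_synthesis	cobL
cobalamin_synthesis	cobH
cobalamin_synthesis	cobB
cobalamin_synthesis	cobN
cobalamin_synthesis	cobS
cobalamin_synthesis	cobT
cobalamin_synthesis	cobO
cobalamin_synthesis	cobQ
cobalamin_synthesis	cobC
cobalamin_synthesis	cobD
cobalamin_synthesis	cobP
cobalamin_synthesis	cobU
cobalamin_synthesis	cobV
cobalamin_synthesis	cobW
cobalamin_synthesis	btuB
cobalamin_synthesis	btuC
cobalamin_synthesis	btuD
cobalamin_synthesis	btuF
cobalamin_synthesis	cbiB
cobalamin_synthesis	cbiZ
cobalamin_synthesis	hemA
cobalamin_synthesis	hemB
glycolysis_em	pgi
glycolysis_em	pfk
glycolysis_em	fba
glycolysis_em	tpi
glycolysis_em	gapA
glycolysis_em	pgk
glycolysis_em	gpmA
glycolysis_em	eno
glycolysis_em	pyk
glycolysis_em	glk
tca_cycle	gltA
tca_cycle	acn
tca_cycle	icd
tca_cycle	kor
tca_cycle	suc
tca_cycle	sdh
tca_cycle	fumC
tca_cycle	mdh
biotin_synthesis	bioA
biotin_synthesis	bioB
biotin_synthesis	bioD
biotin_synthesis	bioF
biotin_synthesis	bioH
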