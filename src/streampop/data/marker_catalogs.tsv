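catalog	marker
trna_synthetases	alaS
trna_synthetases	argS
trna_synthetases	asnS
trna_synthetases	aspS
trna_synthetases	cysS
trna_synthetases	glnS
trna_synthetases	gltX
trna_synthetases	glyS
trna_synthetases	hisS
trna_synthetases	ileS
trna_synthetases	leuS
trna_synthetases	lysS
trna_synthetases	metG
trna_synthetases	pheS
trna_synthetases	pheT
trna_synthetases	proS
trna_synthetases	serS
trna_synthetases	thrS
trna_synthetases	trpS
trna_synthetases	tyrS
trna_synthetases	valS
universal_40	dnaG
universal_40	frr
universal_40	infC
universal_40	nusA
universal_40	pgk
universal_40	pyrG
universal_40	rplA
universal_40	rplB
universal_40	rplC
universal_40	rplD
universal_40	rplE
universal_40	rplF
universal_40	rplK
universal_40	rplL
universal_40	rplM
universal_40	rplN
universal_40	rplP
universal_40	rplR
universal_40	rplS
universal_40	rplT
universal_40	rplV
universal_40	rpmA
universal_40	rpoB
universal_40	rpsB
universal_40	rpsC
universal_40	rpsD
universal_40	rpsE
universal_40	rpsG
universal_40	rpsH
universal_40	rpsI
universal_40	rpsJ
universal_40	rpsK
universal_40	rpsL
universal_40	rpsM
universal_40	rpsO
universal_40	rpsQ
universal_40	rpsS
universal_40	secY
universal_40	smpB
universal_40	tsf
bacterial_178	bhk001
bacterial_178	bhk002
bacterial_178	bhk003
bacterial_178	bhk004
bacterial_178	bhk005
bacterial_178	bhk006
bacterial_178	bhk007
bacterial_178	bhk008
bacterial_178	bhk009
bacterial_178	bhk010
bacterial_178	bhk011
bacterial_178	bhk012
bacterial_178	bhk013
bacterial_178	bhk014
bacterial_178	bhk015
bacterial_178	bhk016
bacterial_178	bhk017
bacterial_178	bhk018
bacterial_178	bhk019
bacterial_178	bhk020
bacterial_178	bhk021
bacterial_178	bhk022
bacterial_178	bhk023
bacterial_178	bhk024
bacterial_178	bhk025
bacterial_178	bhk026
bacterial_178	bhk027
bacterial_178	bhk028
bacterial_178	bhk029
bacterial_178	bhk030
bacterial_178	bhk031
bacterial_178	bhk032
bacterial_178	bhk033
bacterial_178	bhk034
bacterial_178	bhk035
bacterial_178	bhk036
bacterial_178	bhk037
bacterial_178	bhk038
bacterial_178	bhk039
bacterial_178	bhk040
bacterial_178	bhk041
bacterial_178	bhk042
bacterial_178	bhk043
bacterial_178	bhk044
bacterial_178	bhk045
bacterial_178	bhk046
bacterial_178	bhk047
bacterial_178	bhk048
bacterial_178	bhk049
bacterial_178	bhk050
bacterial_178	bhk051
bacterial_178	bhk052
bacterial_178	bhk053
bacterial_178	bhk054
bacterial_178	bhk055
bacterial_178	bhk056
bacterial_178	bhk057
bacterial_178	bhk058
bacterial_178	bhk059
bacterial_178	bhk060
bacterial_178	bhk061
bacterial_178	bhk062
bacterial_178	bhk063
bacterial_178	bhk064
bacterial_178	bhk065
bacterial_178	bhk066
bacterial_178	bhk067
bacterial_178	bhk068
bacterial_178	bhk069
bacterial_178	bhk070
bacterial_178	bhk071
bacterial_178	bhk072
bacterial_178	bhk073
bacterial_178	bhk074
bacterial_178	bhk075
bacterial_178	bhk076
bacterial_178	bhk077
bacterial_178	bhk078
bacterial_178	bhk079
bacterial_178	bhk080
bacterial_178	bhk081
bacterial_178	bhk082
bacterial_178	bhk083
bacterial_178	bhk084
bacterial_178	bhk085
bacterial_178	bhk086
bacterial_178	bhk087
bacterial_178	bhk088
bacterial_178	bhk089
bacterial_178	bhk090
bacterial_178	bhk091
bacterial_178	bhk092
bacterial_178	bhk093
bacterial_178	bhk094
bacterial_178	bhk095
bacterial_178	bhk096
bacterial_178	bhk097
bacterial_178	bhk098
bacterial_178	bhk099
bacterial_178	bhk100
bacterial_178	bhk101
bacterial_178	bhk102
bacterial_178	bhk103
bacterial_178	bhk104
bacterial_178	bhk105
bacterial_178	bhk106
bacterial_178	bhk107
bacterial_178	bhk108
bacterial_178	bhk109
bacterial_178	bhk110
bacterial_178	bhk111
bacterial_178	bhk112
bacterial_178	bhk113
bacterial_178	bhk114
bacterial_178	bhk115
bacterial_178	bhk116
bacterial_178	bhk117
bacterial_178	bhk118
bacterial_178	bhk119
bacterial_178	bhk120
bacterial_178	bhk121
bacterial_178	bhk122
bacterial_178	bhk123
bacterial_178	bhk124
bacterial_178	bhk125
bacterial_178	bhk126
bacterial_178	bhk127
bacterial_178	bhk128
bacterial_178	bhk129
bacterial_178	bhk130
bacterial_178	bhk131
bacterial_178	bhk132
bacterial_178	bhk133
bacterial_178	bhk134
bacterial_178	bhk135
bacterial_178	bhk136
bacterial_178	bhk137
bacterial_178	bhk138
bacterial_178	bhk139
bacterial_178	bhk140
bacterial_178	bhk141
bacterial_178	bhk142
bacterial_178	bhk143
bacterial_178	bhk144
bacterial_178	bhk145
bacterial_178	bhk146
bacterial_178	bhk147
bacterial_178	bhk148
bacterial_178	bhk149
bacterial_178	bhk150
bacterial_178	bhk151
bacterial_178	bhk152
bacterial_178	bhk153
bacterial_178	bhk154
bacterial_178	bhk155
bacterial_178	bhk156
bacterial_178	bhk157
bacterial_178	bhk158
bacterial_178	bhk159
bacterial_178	bhk160
bacterial_178	bhk161
bacterial_178	bhk162
bacterial_178	bhk163
bacterial_178	bhk164
bacterial_178	bhk165
bacterial_178	bhk166
bacterial_178	bhk167
bacterial_178	bhk168
bacterial_178	bhk169
bacterial_178	bhk170
bacterial_178	bhk171
bacterial_178	bhk172
bacterial_178	bhk173
bacterial_178	bhk174
bacterial_178	bhk175
bacterial_178	bhk176
bacterial_178	bhk177
bacterial_178	bhk178
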