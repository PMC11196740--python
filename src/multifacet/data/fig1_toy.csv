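source,target,layer,weight
v01,v02,black,1.000000
v01,v03,black,1.000000
v01,v04,black,1.000000
v01,v05,black,1.000000
v01,v06,black,1.000000
v01,v07,black,1.000000
v02,v01,black,1.000000
v02,v03,black,1.000000
v02,v04,black,1.000000
v02,v05,black,1.000000
v02,v06,black,1.000000
v03,v01,black,1.000000
v03,v02,black,1.000000
v03,v04,black,1.000000
v03,v05,black,1.000000
v03,v06,black,1.000000
v04,v01,black,1.000000
v04,v02,black,1.000000
v04,v03,black,1.000000
v04,v05,black,1.000000
v04,v06,black,1.000000
v05,v01,black,1.000000
v05,v02,black,1.000000
v05,v03,black,1.000000
v05,v04,black,1.000000
v05,v06,black,1.000000
v06,v01,black,1.000000
v06,v02,black,1.000000
v06,v03,black,1.000000
v06,v04,black,1.000000
v06,v05,black,1.000000
v07,v01,black,1.000000
v07,v08,black,1.000000
v07,v09,black,1.000000
v07,v10,black,1.000000
v07,v11,black,1.000000
v07,v12,black,1.000000
v08,v07,black,1.000000
v08,v09,black,1.000000
v08,v10,black,1.000000
v08,v11,black,1.000000
v08,v12,black,1.000000
v09,v07,black,1.000000
v09,v08,black,1.000000
v09,v10,black,1.000000
v09,v11,black,1.000000
v09,v12,black,1.000000
v10,v07,black,1.000000
v10,v08,black,1.000000
v10,v09,black,1.000000
v10,v11,black,1.000000
v10,v12,black,1.000000
v11,v07,black,1.000000
v11,v08,black,1.000000
v11,v09,black,1.000000
v11,v10,black,1.000000
v11,v12,black,1.000000
v12,v07,black,1.000000
v12,v08,black,1.000000
v12,v09,black,1.000000
v12,v10,black,1.000000
v12,v11,black,1.000000
v01,v04,red,1.000000
v01,v05,red,1.000000
v01,v06,red,1.000000
v02,v04,red,1.000000
v02,v05,red,1.000000
v02,v06,red,1.000000
v03,v04,red,1.000000
v03,v05,red,1.000000
v03,v06,red,1.000000
v04,v01,red,1.000000
v04,v02,red,1.000000
v04,v03,red,1.000000
v05,v01,red,1.000000
v05,v02,red,1.000000
v05,v03,red,1.000000
v06,v01,red,1.000000
v06,v02,red,1.000000
v06,v03,red,1.000000
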