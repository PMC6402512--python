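variant_id	effect_allele	beta
rs6733839	T	0.199
rs11136000	T	-0.151
rs3851179	A	-0.128
rs744373	G	0.157
rs9349407	C	0.113
rs3764650	G	0.215
rs3865444	A	-0.062
rs9331896	C	-0.140
rs10948363	G	0.104
rs11218343	C	-0.248
rs17125944	C	0.131
rs10838725	C	0.049
rs983392	G	-0.095
rs10792832	A	-0.117
rs4147929	A	0.148
rs2718058	G	-0.073
rs1476679	C	-0.089
rs10498633	T	-0.086
rs8093731	T	-0.262
rs35349669	T	0.077
rs190982	G	-0.069
rs2279590	T	-0.112
rs28834970	C	0.101
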