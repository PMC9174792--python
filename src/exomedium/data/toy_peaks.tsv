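metabolite	iso_1_r1	iso_1_r2	iso_1_r3	iso_2_r1	iso_2_r2	iso_2_r3	ctrl_r1	ctrl_r2	ctrl_r3	blank_r1	blank_r2
glucose	100018.5	100906.2	101593.8	150375.3	204758.3	158983.0	1990267.2	1664273.7	1816527.3	58324.8	61856.4
proline	83666.5	97813.1	69578.6	98895.2	116682.0	111701.3	913488.0	809189.2	1079954.5	26588.8	22388.7
succinic acid	259122.6	250783.7	268817.9	227584.6	205669.1	259045.7	274854.6	367824.5	336339.6	8910.6	9173.5
adenine	20998.8	21867.1	26638.3	28960.5	27671.2	26572.4	118006.1	95146.7	100243.1	3979.0	3012.8
uridine	16813.3	19372.4	14713.1	19844.7	23826.0	28139.9	61002.5	68255.1	60674.4	2233.5	1650.2
trehalose	775608.4	949492.7	840294.5	890507.1	869656.1	757460.4	908651.9	916257.9	981319.6	24397.7	26217.0
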