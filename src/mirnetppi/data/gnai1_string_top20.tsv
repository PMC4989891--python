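gene	score	binding	inhibition
Gnb1	0.994	1	0
Gnb4	0.98	1	0
Gnb2	0.98	1	0
Rgs19	0.979	1	1
Gnb3	0.978	1	0
Rgs1	0.976	1	1
Plcb1	0.974	1	0
Adcy4	0.973	1	1
Adcy9	0.973	1	1
Rgs14	0.972	1	1
Plcb4	0.97	1	0
Adcy1	0.97	1	1
Plcb3	0.97	1	0
Adcy8	0.969	1	1
Adcy2	0.969	1	1
Rgs10	0.969	1	1
Adcy6	0.967	1	1
Adcy7	0.967	1	1
Adcy5	0.966	1	1
Adcy3	0.966	1	1
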