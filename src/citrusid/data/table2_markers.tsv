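target	marker	source	fragment_size_bp
*	rbcL	positive_control	622
Asumi	Cp0419-s	InDel	371
Asumi	IND214-s	InDel	246
Rinoka	IND141-l	InDel	246
Mihaya	Tcs2-CL55_M	Tcs2	279
Mihaya	Tcs1-P86	Tcs1	182
Asuki	Tcs2-CL25	Tcs2	243
Asuki	IND235-s	InDel	144
Ehimekashidai28go	Tcs2-CL68	Tcs2	185
Kanpei	Cp0419-s	InDel	246
Kanpei	IND265-l	InDel	280
Kanpei	IND44-l	InDel	152
Himekoharu	Tcs2-CL80	Tcs2	262
Ehimekashidai48go	Tcs2-CL55_E	Tcs2	263
Ehimekashidai48go	Tcs1-CL26	Tcs1	160
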