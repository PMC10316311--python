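marker	Miyagawa-wase	Duncan	Trovita	Lisbon	Shiranuhi	Iyo	Kawanonatsudaidai	Hassaku	Ohta-ponkan	Rinoka	Mihaya	Asumi	Asuki	Reikou	Tsunokagayaki	Seinannohikari	Tsunonozomi	Haruhi	Kiyomi	Setoka	Harumi	Harehime	Kanpei	Ehimekashidai28go	Himekoharu	Ehimekashidai48go
rbcL	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○	○
Cp0419-s	×	×	×	×	○	×	×	×	○	×	×	○	×	×	×	○	×	×	×	×	○	×	○	×	×	×
IND214-s	×	○	○	×	×	○	○	○	×	×	×	○	○	×	×	×	×	○	×	×	×	×	×	×	○	×
IND141-l	×	×	×	×	×	×	×	×	×	○	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×
Tcs2-CL55_M	×	×	×	×	×	×	×	×	×	×	○	×	×	×	×	×	○	×	×	×	×	×	×	○	×	○
Tcs1-P86	○	×	×	×	×	×	×	×	×	×	○	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×
Tcs2-CL25	×	×	×	×	○	×	×	×	○	×	×	○	○	×	×	○	×	×	×	×	○	×	○	×	×	○
IND235-s	×	×	○	×	×	×	×	×	×	×	×	×	○	×	×	×	×	×	○	○	×	×	×	×	×	×
Tcs2-CL68	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	○	×	×
Cp0419-s	×	×	×	×	○	×	×	×	○	×	×	○	×	×	×	○	×	×	×	×	○	×	○	×	×	×
IND265-l	○	○	○	×	×	×	○	×	×	○	×	○	○	×	×	×	×	○	×	×	×	×	○	×	○	×
IND44-l	○	○	○	○	○	×	×	×	×	○	×	×	○	×	○	○	×	×	○	×	×	○	○	×	○	×
Tcs2-CL80	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	×	○	×
Tcs2-CL55_E	×	×	×	×	×	×	×	×	×	×	○	×	×	×	×	×	○	×	×	×	×	×	×	○	×	○
Tcs1-CL26	×	×	×	×	○	○	×	×	○	×	×	×	×	×	×	○	×	×	×	×	×	×	○	×	×	○
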