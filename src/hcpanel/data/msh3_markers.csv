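Family,Patient,Site,IHC_Normal,IHC_Tumor,BAT25,BAT26,D2S123,D5S346,D17S250,D18S69,D18S64,MYCL1,D20S82,D9S242,D20S85,L17835,D19S394,D8S321
22,Proband,Breast,3+,2+,-,-,-,-,-,-,-,-,-,-,-,+,+,+
22,Mother,Breast,2+,2+,-,-,-,-,-,+,+,-,-,-,-,-,-,-
49,Proband,Breast,3+,2+,-,-,-,-,-,-,-,-,-,-,-,-,-,+
49,Proband,Ovary,2+,0,-,-,-,-,-,-,-,-,+,-,-,-,+,-
49,Mother,Breast,1+,1+,-,-,-,-,-,-,-,+,-,-,-,-,-,-
49,Mother,Colon,2+,2+,-,-,-,-,-,-,-,-,-,-,-,-,+,-
75,Proband,Breast,3+,3+,-,-,-,-,-,-,-,-,-,-,+,-,-,-
75,Sister,Breast,3+,1+,-,-,-,-,-,+,-,+,-,+,-,-,-,+
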