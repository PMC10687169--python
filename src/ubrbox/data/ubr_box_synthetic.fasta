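>UBR1 synthetic UBR-box stand-in sequence
TQKICAHCGLEFQPSQGVLCAECKRACGTCTMRNAGSGDLAHALRHAKKGKIVMAFGDPCNECDRWHFEALR
>UBR2 synthetic UBR-box stand-in sequence
TDKVCGHCSLEFNSNQAVLCSECKHACGTCSMHNPGAADLAHGLRHAKQGKIVMAFGDPCQQCDRFHFEALQ
>UBR3 synthetic UBR-box stand-in sequence
TDKVCGYCGLEFNSSATLCAECKRACSTCALRSPGDLGHGLRHVKEAKIVMTFGDPCNECDKWHFKSLR
>UBR4 synthetic UBR-box stand-in sequence
TDKVCGYCGLEFNPSQAVLCSECKRACGTCAIRNPGDLAHGLRHAKEGKIVMSFGDPCNECDRWCFEALR
>UBR5 synthetic UBR-box stand-in sequence
SDKICGWCALEFNSSQALLCSECKRACATCAIHNPADLAHGLRHAKEGKITLSFGDPCNKCDKWCFEAMH
>UBR6 synthetic UBR-box stand-in sequence
TDKVCGYCNLEFNPAQAIVCSECERACATCVVNPADIAHALHHAREGKIVISFGDPCNDCDRWCFESIR
>UBR7 synthetic UBR-box stand-in sequence
TNRVCNYCGLEFNSAQAVLCSECERACASCAIRNPGDLAHNLRHAKNKGKIVVSFSDPCQECDRFCYQVLR
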