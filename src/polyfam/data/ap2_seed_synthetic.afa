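>ap2_seed_erf_1
MRGVRQRPWGKWVAEIRDDPRRGAGLWLGGFDYAEEAARMYDEAARAMYGIRARTNFPVN
>ap2_seed_erf_2
YRGLRQRTWGKWVAEIRDDPRRGCRLWLGEFDTQEEAARAYDEAARAMYGPRARTNFFVN
>ap2_seed_erf_3
YRSVRQRFKGKQVAEIRDDPRRGARLWLGTFDTAVEAARAYDEAARAMYTPRARTNFPVN
>ap2_seed_erf_4
YRNVRQRPMGGWVAEIRDDPRRGARLWLLTEDTAEFAARAYDEAARAMYGPRARTNFPVN
>ap2_seed_erf_5
YRGVCQRPPGKWVAEIRDDPRRGARLWLGTFTTAECAARALDEAARAMYGPRARTNFPVD
>ap2_seed_erf_6
YRGVRQRPWGKWVAEIRLDPRRGNYLWLGTFDDAEEAARAYDEAARAMYGPRAATNFPVY
>ap2_seed_erf_7
YRGVRQRSWGKWVAHIRDDPRRGASLGLGTFDTAEEAARAYDEAHRAMYGPRARTTFPVN
>ap2_seed_erf_8
YRTVRQRPWGKKVAEIRDDPRRGAVLWLGFFDTAEEAARAYFEAARAMYGPRARTNFPVW
>ap2_seed_erf_9
YRFWRQRIWGKWVAEIRDDPRRGARLWLGTFDTGEWAARAYDEAARAMYGGRARTNFPVN
>ap2_seed_erf_10
YRGVRQRPWGKWVAQIEDDPRRGQRLDYGTFDTAEEAARAYREAARAMYGPRARTNFPVN
>ap2_seed_erf_11
YRGNRQRPWGKWVAEIRDDPARGARLWLGTFDTAEEAAWLYDEAARIMYGPRARTNFRVN
>ap2_seed_erf_12
YRAVRQRPWLKWVAEIRDDPRRGAWLWHGTFDTAEEAARAYDEAARAMYGPRARMNFPPN
>ap2_seed_erf_13
YRHVWQRPWGKWVADIRDDPRRGARLWPGTFDTAEEKARAYDEHARAMYGPRARTNFPVN
>ap2_seed_erf_14
YCGVRQRPWGKWVAEIRDDPRRGARIWLGTFDTAEEAARAYDEAARAMYGPRARWSMPVP
>ap2_seed_erf_15
YRGVRQRPWGKWVAEIRDDPRRGARLLLGTLDTAKETATAYDEAADAMYGPRARTNFPVN
>ap2_seed_erf_16
YRGVRQRPWGKWDAEIPDDPRRGKRLWLGTFDTATEFARAYDEAARAMYQPRARTNFPVN
>ap2_seed_erf_17
YRGVRQRWWGKWVAEIRDDPRRGARLWLGTWDQAEEAARAYDEAALAMYGPMARTSFPVN
>ap2_seed_erf_18
YRGVRQRPWGKWVAEIRDDMRRPARLWLGTFDTAEFAARAYDEANCAMYGPSARTNFPVN
>ap2_seed_erf_19
YRGVRQRPPGKWVAEIRDDPRFGARLWLGTFDTAELMARARDEAARAMYGPRAYTNFPVN
>ap2_seed_erf_20
YRGVRVRPWGKWVAEIRDDFRRGMRLWLGTFDKAEEAARCYDEAARAMYGPRARTNFPWN
>ap2_seed_dreb_1
YRGVRQRPWGKWVVIIRDEPRRGERMWLGTMDTAEEAACAYDEAARAMYGPRARTNYPVN
>ap2_seed_dreb_2
YRGVRQMPWGKWVVEIRDEPRRGARLWLGTFDTAEEACRMYDSAARAMYGPRARTLFPIN
>ap2_seed_dreb_3
YRGVRQRPWGKWVVEIRDAVRRGTRLWLGTFDTAEEAARAYDSAARAMYSPRARTNFAVG
>ap2_seed_dreb_4
YRGVRQRPWGKKVVEIRDLPRKGARLWLGTFDTAEEAARAYDEAVRAMYIFRAVTNFPVN
>ap2_seed_dreb_5
YRGVRQREWGKWVVEIIDEPRRGARLWQGTHDTAEEAARAYDHAARAMYGPRARTEFPVN
>ap2_seed_dreb_6
YRGVRQPPWGKWVVEMRDEPRRGARLWLGTFDTACEAARAYDEAAKTMYGPRGRTNFPVN
>ap2_seed_dreb_7
YRGVRQRPWGKWVVVIRDAPRRGARLWLGTNGTAEEWARAYDEAARCMYGYRARTNFPVN
>ap2_seed_dreb_8
YRGGRQFPWGKWVVEIRDLPRRHARIWLGTIDTAENAARAYDEAARAMYGPRARTNFPVN
>ap2_seed_dreb_9
YRGVRRRPWGKWVVEIRREPRRGARLWLGTFDTQEEAARAYDEAAIAMYGQRARTKFPVN
>ap2_seed_dreb_10
YRGVRQRPYGKWVVEIRDEPPRGARKWLGTFDTAEEAQRAYDEAAEAMYGPRARSNFPVN
>ap2_seed_dreb_11
YRGVRQMPWGKWVVEIRDAPRRGARLWGGTGDTAEEAARAYDEYARAMSGPMARTNFPVN
>ap2_seed_dreb_12
YRGVRQRPWWKWVVEPRDLPRRGARNWLGTADTAEEAARAYDEAARAMYEPRARTNFVVN
>ap2_seed_dreb_13
YRGVRQRPWGKNVVEIPDEWRQGARLWLGTFDTAEEAQDAYDEAARAMYGPRARTNFPVN
>ap2_seed_dreb_14
YRGVRQRPWGKWVVEIRDEVDRDARLWLGTFDTAEKHARANDEAARAMYGPRARTNFPVN
>ap2_seed_dreb_15
YRGVRQRPWGKWVVAIRDAPRRGARLWDVTFFTAEEADRAYDEAARAMYGCRARTNFPVN
>ap2_seed_dreb_16
YRFVRQRPWGKWVVKIRDLPRRGARLWLETFDTAEEAMRAYDEAARASYGARARTNFPVN
>ap2_seed_dreb_17
YRGVLQRVWKYWVVEIRDEPRRGARLWLGKFDTAEEAARAYDEAARAKYGPRARTNFPVN
>ap2_seed_dreb_18
YRGVRQRPWGKWVVEIRDEERKGARLWLGTFDTAEAAARAYDEAAFAMYGPRRDTNFPVN
>ap2_seed_dreb_19
YRGVRMRPWGKWVVEIRDAPRRGARCWLGTFDTAEEAARDYDFAAQAMYGPRARTNCPVN
>ap2_seed_dreb_20
YRGVRQRWWGNWVVEIRDLPSRGARLWLGTFDTACEIARAYDEAAYAMYGPRARTNFPVN
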