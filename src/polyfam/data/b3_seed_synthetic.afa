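>b3_seed_1
FKKLTPSDVSKRLRLPEKFVRNYGDELSDTVTWEVRSGRTWHAELEKSDG
>b3_seed_2
PKNLTPSDVSKRLRLPETFVWNYGDELPDTVTLEVPSGRTWHVELTKSDG
>b3_seed_3
FKVLTPSDVSKRLRLPEKFVGNYGCELSDCKTLEVPSERTWHVELTKSDG
>b3_seed_4
FKVLTPSDVSKRLRLPEKHVRNYGDHLSDTKTLEVPSGRTWHVELTKRDK
>b3_seed_5
FKVLTPSDVSKRTRLPEKFVRNYGDELSDTVTLEVPMCRTWHVELTKLTG
>b3_seed_6
FKVLTPSDVGTRFRLPEKFVRNYGDELSDTVTLWVPSGRTWHVELTKCDG
>b3_seed_7
FKVLTPSDVSKRLRLPEKFVRQYGDKCLDTVTLEVPSGRTWHVELTKSDI
>b3_seed_8
CKVLTPSDVSKRLRLPEKFVKNYLDELSDTVTLEVPVGRRWHVELTKSDG
>b3_seed_9
FKVLTPNDVSKRLRLPEKFVRNYVDELSDTVTLEVMAGRTWHVILTKSDG
>b3_seed_10
FKVMTPSDVSKRLRLFEKFVRNYGQELSDTVTLEWPSGRTWHTELTKSDG
>b3_seed_11
FKVLTPSDVKKRLRDPEKFVRNYGDELSDPVTLEVPSPRTWHVSLTKSDG
>b3_seed_12
FKVLTFRDVSKRLRLPEKFVRNYWDELSDTVTLEVPIGRFWHVELTKSDG
>b3_seed_13
FKVLTPSDVLKRLWDPEKFVRFYGDELSDMVTLEVPSGRTWHVELTKSDG
>b3_seed_14
FKVLTPSDVSGRLRLPEKFVRNYGDEGPDTVTLEVPSGRTWHDELTISDG
>b3_seed_15
FTVLTPSDVYKRLRLPEKFVRNYGDELSDTFTLEVPSVRTWWVELTKSDG
>b3_seed_16
FKVSTNSDVSKRLRLPEKFVRMYGDELSDTVTYEVPSGRTWHVELTCSDG
>b3_seed_17
FKRLTPSDVSKRLRLWEKFVRNYGDELSDTVTLEVPMGRTWHVELVKSWG
>b3_seed_18
EKVLTPSSVSKRLRLPEKFVRNYGDELSDTPTLEVPSGRTWSVELTKSDE
>b3_seed_19
FKVLLPSDVSKRLRLPEKFVVTYGDELSDTVTLEFPSGRTWHVELTKSDK
>b3_seed_20
FKVLTPSDVSRRLRLPEKFCRNYGDELSDTVTLEVPSGDTWHVEWRKSDG
>b3_seed_21
FKVLTPSDVSKRLRLPEKFHRNYGDELHYKNTLEVPSGRTWHVELTKSDG
>b3_seed_22
FKKLTPSDVHKRLRLPEKFGRNYGDALSDTVTLEVWSGRTWHVELTKSDG
>b3_seed_23
FEVLTPGDVKKRLRLPEMFVRNYGDELSDTVTLEVPSGRTWHHELTKSDG
>b3_seed_24
FKVLTPSGVSKRLRLPEEFVRNYGDWLCDTVTLEVPSGRTCHVELTKSDG
>b3_seed_25
FKVLTPSDVSKQCRLPEKFVRNYGDELSDTVGLEVPSWRTWHVELVKSDG
>b3_seed_26
FKVLTPSDVSKRFGEPEKFVRNYGDELSDTVTLEVPSGRTWHVELGKSDW
>b3_seed_27
FKVLTPQHVSKRLRLPEKFVRNYGDELSDTVTLEVPHGRTWHVELTKSKI
>b3_seed_28
FTVLTPSIWSKRLRLPEKFVRNYGDELSYTVTLEVPSPRTWHVELTKSDG
>b3_seed_29
FKVLTPKDVKKRLRLPEKFARNYGDELSDNVTLEFPSGRTWHVELTKSDG
>b3_seed_30
FKRLTPSDVSKRLRLPEKFVRNYGDELSDTVTLEVPSFRTQHVVLTKFDG
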