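>A1_1 subfamily=DREB group=A1
YRGVRQRPWGKWVVEIRDEPPCDPDLWLGTFDTAEEAARAYDEAARAMYGPRARTNFPVN
>A1_2 subfamily=DREB group=A1
YRGVRQRPWGKWVVEIRDEPPCDPDLWLGTFDTAEEAARAYDEAARAMYGPRARTNFDVN
>A1_3 subfamily=DREB group=A1
YRGVRQRPWGKWVVEIRDEPPCDPDLWLGTFDTAEEAARAYDEAARAMYGPRARTNFPQN
>A2_1 subfamily=DREB group=A2
YRGVRQRPWGKWVVEIRDEPRRGARDACCEFDTAEEAARAYDEAARAMYGPRARTNFPVN
>A2_2 subfamily=DREB group=A2
YRGVRQRPWGKWVVEIRDEPRRGARDACCEFDTAEEAARAYDEAARAMYGPRARTNFPIN
>A2_3 subfamily=DREB group=A2
YRGVRQRPWGKWVVEIRDEPRRGARDACCEFDTAEEAARAYDEAARAMYGPRARTNFPVI
>A3_1 subfamily=DREB group=A3
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTIWKPCEAARAYDEAARAMYGPRARTNFPVN
>A3_2 subfamily=DREB group=A3
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTIWKPCEAARAYDEAARAMYGPRARTNFPVE
>A3_3 subfamily=DREB group=A3
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTIWKPCEAARAYDEAARAMYGPRARTTFPVN
>A4_1 subfamily=DREB group=A4
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAENFNNSYDEAARAMYGPRARTNFPVN
>A4_2 subfamily=DREB group=A4
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAENFNNSYDEAARAMYGPRARTWFPVN
>A4_3 subfamily=DREB group=A4
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAENFNNSYDEAARAMYGPRARTNAPVN
>A5_1 subfamily=DREB group=A5
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAEEAARAHCSGMRAMYGPRARTNFPVN
>A5_2 subfamily=DREB group=A5
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAEEAARAHCSGMRAMYGPRARTNPPVN
>A5_3 subfamily=DREB group=A5
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAEEAARAHCSGMRAMYGPRARTNFSVN
>A6_1 subfamily=DREB group=A6
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAEEAARAYDEAALKATAPRARTNFPVN
>A6_2 subfamily=DREB group=A6
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAEEAARAYDEAALKATAPRARTNFKVN
>A6_3 subfamily=DREB group=A6
YRGVRQRPWGKWVVEIRDEPRRGARLWLGTFDTAEEAARAYDEAALKATAPRARTNFPYN
>B1_1 subfamily=ERF group=B1
YRGVRQRPWGKWVAEIRDDPWLTKILWLGTFDTAEEAARAYDEAARAMYGPRARTNFPVN
>B1_2 subfamily=ERF group=B1
YRGVRQRPWGKWVAEIRDDPWLTKILWLGTFDTAEEAARAYDEAARAMYGPRARTNFVVN
>B1_3 subfamily=ERF group=B1
YRGVRQRPWGKWVAEIRDDPWLTKILWLGTFDTAEEAARAYDEAARAMYGPRARTNFPGN
>B2_1 subfamily=ERF group=B2
YRGVRQRPWGKWVAEIRDDPRRGARQCPVSFDTAEEAARAYDEAARAMYGPRARTNFPVN
>B2_2 subfamily=ERF group=B2
YRGVRQRPWGKWVAEIRDDPRRGARQCPVSFDTAEEAARAYDEAARAMYGPRARTNFPYN
>B2_3 subfamily=ERF group=B2
YRGVRQRPWGKWVAEIRDDPRRGARQCPVSFDTAEEAARAYDEAARAMYGPRARTNFPVY
>B3_1 subfamily=ERF group=B3
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTHPVLAEAARAYDEAARAMYGPRARTNFPVN
>B3_2 subfamily=ERF group=B3
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTHPVLAEAARAYDEAARAMYGPRARTNFPVQ
>B3_3 subfamily=ERF group=B3
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTHPVLAEAARAYDEAARAMYGPRARTIFPVN
>B4_1 subfamily=ERF group=B4
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEPLGVMYDEAARAMYGPRARTNFPVN
>B4_2 subfamily=ERF group=B4
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEPLGVMYDEAARAMYGPRARTLFPVN
>B4_3 subfamily=ERF group=B4
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEPLGVMYDEAARAMYGPRARTNCPVN
>B5_1 subfamily=ERF group=B5
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAWNTKTRAMYGPRARTNFPVN
>B5_2 subfamily=ERF group=B5
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAWNTKTRAMYGPRARTNVPVN
>B5_3 subfamily=ERF group=B5
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAWNTKTRAMYGPRARTNFCVN
>B6_1 subfamily=ERF group=B6
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAYDEAAGRFCDPRARTNFPVN
>B6_2 subfamily=ERF group=B6
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAYDEAAGRFCDPRARTNFYVN
>B6_3 subfamily=ERF group=B6
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAYDEAAGRFCDPRARTNFPWN
>B7_1 subfamily=ERF group=B7
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAYDEAARAMYGFWYAENFPVN
>B7_2 subfamily=ERF group=B7
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAYDEAARAMYGFWYAENFPNN
>B7_3 subfamily=ERF group=B7
YRGVRQRPWGKWVAEIRDDPRRGARLWLGTFDTAEEAARAYDEAARAMYGFWYAENFPVR
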