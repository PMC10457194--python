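>KC0001 NFKB_kB
A  [  2  2  2 47 25 25  3  3  2  2 ]
C  [  2  2  2  3 25 25 47 47 94 94 ]
G  [ 94 94 94 47 25 25  3  3  2  2 ]
T  [  2  2  2  3 25 25 47 47  2  2 ]
>KC0002 PU1_ETS
A  [  2 94  2  2 94 94 ]
C  [  2  2  2  2  2  2 ]
G  [ 94  2 94 94  2  2 ]
T  [  2  2  2  2  2  2 ]
>KC0003 IRF_core
A  [ 94 94 25 25  2 94 94 94 ]
C  [  2  2 25 25  2  2  2  2 ]
G  [  2  2 25 25 94  2  2  2 ]
T  [  2  2 25 25  2  2  2  2 ]
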