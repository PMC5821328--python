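>SINV5_like
CSQNPVCQFCMSRHRSKDTLHIESSPNNAKLCNNNCVTGPESRICYKVQSSEILLAMERQGDDYKHWICLSMLDQLHFNQ
>ABPV_like
CSQNPVCQFCMSRHRSKDTLHIEPSPNNAKLCTNVCVTGPESRICYKVQSSEELLAMERQGDDYKHWICLSELDQLHHNQ
>IAPV_like
CQQNPVCQRCMSRHRSKDTLHIEPSPLNAKLCNNVCVTGPESRICYKVQSSEILLAMERQGDDYKHWICLSELDQLHFNQ
>KBV_like
CSQNPVCQFCMSLHRSKDTLHIEPSPNNAKLCNNVCVTGPESRICYKVQSSEILLEMERQGDDYKHWICLSEQDQLHFNQ
>ALPV_like
CSQKKVCQFCMYRQRSMDTLMIEWSPKTMKPFCNPCVTGPVSRICYKVQYSEILLAFFRQGDDCTHWIGLSALDGLHKNQ
>RhPV_like
CSQKKVCHFCMYRSRSMDTLMIEWSPKTYKLFCNVCVTGPVSRICYKVQYSEILLAFFRQGDDCTHWIGLSALDGIHKNQ
>HiPV_like
CSQKKVCQFCMYRSRSMDTLMIEWSPKTMKLFCNVCVTGGVSRICYKVQYSEILLSFFRQGDDCTHWIGLYALDGLHKNQ
>TrV_like
CSQKKVCQFCMYRSRSMDTLRIEWSPKTMKLFCNVCVTGPVSRICYKVQYSEILLAFCRQGDDCTHWIGLSALDGLHKNQ
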