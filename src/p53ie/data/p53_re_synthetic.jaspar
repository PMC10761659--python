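>MA0106.3-like synthetic_p53_response_element
A [ 10   8  50   2  70  20   3   5   5   5  10   8  15   2  70  20   3   5   5   5 ]
C [  5   4   5  92   5   5   2  35  60  70   5   4   5  92   5   5   2  35  60  70 ]
G [ 80  84  40   2   5   5  90   5   5   5  80  84  75   2   5   5  90   5   5   5 ]
T [  5   4   5   4  20  70   5  55  30  20   5   4   5   4  20  70   5  55  30  20 ]
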