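>P00709 LALBA_HUMAN Alpha-lactalbumin precursor (142 aa, signal peptide 1-19, mature chain 20-142)
MRFFVPLFLVGILFPAILAKQFTKCELSQLLKDIDGYGGIALPELICTMFHTSGYDTQAI
VENNESTEYGLFQISNKLWCKSSQVPQSRNICDISCDKFLDDDITDDIMCAKKILDIKGI
DYWLAHKALCTEKLEQWLCEKL
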