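{
"AAA": 0.03725819,
"AAC": 0.00118297,
"AAG": 0.01421422,
"AAT": 0.00502657,
"ACA": 0.07469592,
"ACC": 0.01891079,
"ACG": 0.00306495,
"ACT": 0.02563152,
"AGA": 0.00839692,
"AGC": 0.01968121,
"AGG": 0.00363928,
"AGT": 0.03330785,
"ATA": 0.0265799,
"ATC": 0.02541144,
"ATG": 0.0018683,
"ATT": 0.01796518,
"CAA": 0.01011118,
"CAC": 0.02663878,
"CAG": 0.03339559,
"CAT": 0.01060393,
"CCA": 0.00163907,
"CCC": 0.01665176,
"CCG": 0.00335227,
"CCT": 0.00372086,
"CGA": 0.00949325,
"CGC": 0.0076463,
"CGG": 0.00992226,
"CGT": 0.03224638,
"CTA": 0.01054159,
"CTC": 0.0295232,
"CTG": 0.05963649,
"CTT": 0.00212373,
"GAA": 0.01918651,
"GAC": 0.02729174,
"GAG": 0.001591,
"GAT": 0.00495531,
"GCA": 0.03559516,
"GCC": 0.02550499,
"GCG": 0.01881475,
"GCT": 0.01386219,
"GGA": 0.01194371,
"GGC": 0.04299164,
"GGG": 0.01178724,
"GGT": 0.00898372,
"GTA": 0.00108939,
"GTC": 0.01645867,
"GTG": 0.01686175,
"GTT": 0.00541629,
"TAC": 0.00289742,
"TAT": 0.00176291,
"TCA": 0.00170558,
"TCC": 0.0286633,
"TCG": 0.06156236,
"TCT": 0.00182076,
"TGC": 0.01349256,
"TGG": 0.00091166,
"TGT": 0.00163849,
"TTA": 0.00695239,
"TTC": 0.01057754,
"TTG": 0.01783535,
"TTT": 0.00376379
}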