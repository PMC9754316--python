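{
  "comment": "STO-3G minimal basis: primitive exponents and contraction coefficients per shell. Shared 1s/2s/2p contraction coefficients; exponents per element.",
  "coefficients": {
    "1s": [0.1543289673, 0.5353281423, 0.4446345422],
    "2s": [-0.09996722919, 0.3995128261, 0.7001154689],
    "2p": [0.1559162750, 0.6076837186, 0.3919573931]
  },
  "elements": {
    "H":  {"shells": [["s", "1s", [3.425250914, 0.6239137298, 0.1688554040]]]},
    "He": {"shells": [["s", "1s", [6.362421394, 1.158922999, 0.3136497915]]]},
    "Li": {"shells": [["s", "1s", [16.11957475, 2.936200663, 0.7946504870]],
                       ["s", "2s", [0.6362897469, 0.1478600533, 0.0480886784]],
                       ["p", "2p", [0.6362897469, 0.1478600533, 0.0480886784]]]},
    "Be": {"shells": [["s", "1s", [30.16787069, 5.495115306, 1.487192653]],
                       ["s", "2s", [1.314833110, 0.3055389383, 0.0993707456]],
                       ["p", "2p", [1.314833110, 0.3055389383, 0.0993707456]]]},
    "B":  {"shells": [["s", "1s", [48.79111318, 8.887362172, 2.405267040]],
                       ["s", "2s", [2.236956142, 0.5198204999, 0.1690617600]],
                       ["p", "2p", [2.236956142, 0.5198204999, 0.1690617600]]]},
    "C":  {"shells": [["s", "1s", [71.61683735, 13.04509632, 3.530512160]],
                       ["s", "2s", [2.941249355, 0.6834830964, 0.2222899159]],
                       ["p", "2p", [2.941249355, 0.6834830964, 0.2222899159]]]},
    "N":  {"shells": [["s", "1s", [99.10616896, 18.05231239, 4.885660238]],
                       ["s", "2s", [3.780455879, 0.8784966449, 0.2857143744]],
                       ["p", "2p", [3.780455879, 0.8784966449, 0.2857143744]]]},
    "O":  {"shells": [["s", "1s", [130.7093214, 23.80886605, 6.443608313]],
                       ["s", "2s", [5.033151319, 1.169596125, 0.3803889600]],
                       ["p", "2p", [5.033151319, 1.169596125, 0.3803889600]]]}
  }
}
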