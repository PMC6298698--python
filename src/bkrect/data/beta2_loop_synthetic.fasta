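>KCNMB2_beta2_synthetic synthetic stand-in for the human BK beta2 subunit; encodes the loop landmarks (C84,C97,C101,C105,C113,C142,C148,C174; Q83,N88,N96,S100,D104,L114,K137,K141,S143,K147,S173,Y175; sequons N88,N96) with mass-calibrated filler
ELGLFGYRILQVYGGHSHMQHMAAWSKFDHSIDSAKFILDLQAEMRDIQARLIQHMRVVK
KVGGRVSYEITSTLVDLIEDYDQCMEFNATMFGLQNCSTSCHLDCKYLFESVCLATGGVY
AIYEIRTGRRDDKFKTKVGVKCSIQIKCKILEVSQLSATILYHHWHFLIAFTSCYFFHSG
FLQYMELKEIVYAMDTTKKYFKERFDMYHVHVITWKSTVDQHEEHAYDEWDEFVH
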