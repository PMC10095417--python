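>nisin_A mature core, Lactococcus lactis
ITSISLCTPGCKTGALMGCNMKTATCHCSIHVSK
>nisin_F mature core, Lactococcus lactis
ITSISLCTPGCKTGALMGCNMKTATCHCSVHVSK
>nisin_S mature core, Ligilactobacillus salivarius
ITSYSLCTPGCKTGALMGCTMKTASCGCHVHISK
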