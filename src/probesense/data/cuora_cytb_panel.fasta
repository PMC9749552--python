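>ssBT 5mod=HS-S-(CH2)6 thiolated Cuora amboinensis cytb capture probe (31-mer)
GATCATTACTAGGCACCTGCCTAATCCTTCA
>RC reverse complementary target ssDNA
TGAAGGATTAGGCAGGTGCCTAGTAATGATC
>1MN RC one-base-mismatch ssDNA
TGAAGGATTAGGCAAGTGCCTAGTAATGATC
>3MN RC three-base-mismatch ssDNA
TGAAGGATTAGGTGAGTGCCTAGTAATGATC
>CW cow RC ssDNA
TGTAGGATTAGGCAGATTCCCAGGAGGGAAC
>BF buffalo RC ssDNA
TGCAGGATTAGGCAGATGCCTAGGAGAGAGC
>GT horse RC ssDNA
TGGAGGATTAGGCAGATTCCTAGGAGGGAGC
>CK duck RC ssDNA
TGTAGAATCAAGCATACTCCTAGTAAGGATC
>NC noncomplementary control ssDNA
CAGGAAGCCGAATGAACATTCGACGGCAGCT
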