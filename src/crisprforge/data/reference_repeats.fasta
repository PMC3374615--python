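>AhydrL30 Anaerococcus hydrogenalis DSM 7454
ATTTCAATACATCTAATGTTATTAATCAAC
>AlactL29 Anaerococcus lactolyticus ATCC 51172
AGGATCATCCCCGCTTGTGCGGGTACAAC
>BcoprL32 Bacteroides coprophilus DSM 18228
GTCGCACCCTGCGTGGGTGCGTGGATTGAAAC
>FalocL36 Filifactor alocis ATCC 35896
TTTGAGAGTAGTGTAATTTCATATGGTAGTCAAAC
>GhaemL36 Gemella haemolysans ATCC 10379
GTTTGAGAGATATGTAAATTTTGAATTCTACAAAAC
>LcrisL29 Lactobacillus crispatus ST1
AGGATCACCTCCACATACGTGGAGAATAC
>LjassL36 Lactobacillus gasseri JV-V03
GTTTTAGATGGTTGTTAGATCAATAAGGTTTAGATC
>LjensL36 Lactobacillus jensenii 115-3-CHN
GTTTTAGAAGGTTGTTAAATCAGTAAGTTGAAAAAC
>Neis_t014_L28 Neisseria sp. oral taxon 014 str. F0314
GTTACCTGCCGCACAGGCAGCTTAGAAA
>Neis_t014_L36 Neisseria sp. oral taxon 014 str. F0314
GTTGTAGCTCCCTTTCTCATTTCGCAGTGCTACAAT
>PacneL29 Propionibacterium acnes J139
GTATTCCCCGCCTATGCGGGGGTGAGCCC
>PpropL29 Pelobacter propionicus DSM 2379
CGGTTCATCCCCGCGCATGCGGGGAACAC
>SmutaL36 Streptococcus mutans NN2025
GTTTTAGAGCTGTGTTGTTTCGAATGGTTCCAAAAC
>SRS012279L38 HMP tongue dorsum sample SRS012279
TATAAAAGAAGAGAATCCAGTAGAATAAGGATTGAAAC
>SRS018394L37 HMP supragingival plaque sample SRS018394
GTATTGAAGGTCATCCATTTATAACAAGGTTTAAAAC
>SRS023604L36 HMP posterior fornix sample SRS023604
GTTTGAGAGTAGTGTAATTTATGAAGGTACTAAAAC
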