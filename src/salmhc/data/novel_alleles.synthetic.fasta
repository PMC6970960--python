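>AS7UBAs1 synthetic novel (2 aa from UBA*35:01) sequence
CCACAAACTTTCGGTCCCTCATGCCTGGGAATAGGCCTTCTACATGAGCGTCGGGCCATT
TCAGTCCATACTCGTGGCATCTGCAGTAACCCACTCGCTGTATTGTGGCCTTTCATGATC
TACAGTATGTTGGGACTTGACGACCTCTATACCATTCGACATTTATCGCTGCTGCCGGGA
AGGAGCGCTTTTGCCTCTCACGCGCATTATCTAAGTCGATCAAACTATCCAAAAAGCTCC
CACCCTGTTATGCATACAGTAGGTTCTGGTGGGAACCTGGCCCGGTCACGCTGGTTCCCG
GCTGCGATGCTTAGAGGGTGCCCAAAGAAGGATTCTCATCTCAGAAACGCAGGCGTATAT
GTAGATGTAATACAGTCCAAGGTAATGAATCGGCGTTGTGGCTTGTCAGACCTTCTGTGG
TTTTGCGTGAATCTAGTGTACCAATACAGACCGACTCGGGCACATTCCCGGGACAGCAGT
TGTATGAATAAATATGTGGCTGAAGAAGTATCTGGACCACAAACCTCAAGAGGCCCAGGC
>AS2UBAs1 synthetic novel new-group sequence
CCACAAACTTTCGGTCCCTCATGCCTGGGAATAGGCCTTCTACATGAGCGTCGGGCCATT
TCAGTCCATACTCGTGGCATCTGCAGTAACCCACTCGCTGTATTGTGGCCTTTCATGATC
TACAGTATGTTGGGACTTGACGACCTCTATACCATTCGACATTTATCGCTGCTGCCGGGA
AGGAGCGCTTTTGCCTCTCACGCGCATTATCTAAGTCGATCAAACTATTGCTATTGGGCT
TCTAATCCCTCCCAACATAAAGTCTCTGGTGGGAACCTGGCCCGGTCACGCTGGTTCCCG
GCTGCGATGCTTAGAGGGTGCCCAAAGAAGGATTCTCATCTCAGAAACGCAGGCGTATAT
TGTGCTGTAATACAGTCCAAGGTAATGAATCGGCGTTGTGGCTTGTCAGACCTTCTGTGG
TTTTGCGTGAATCTAGTGTACCAATACAGACCGACTCGGGCACATTCCCGGGACAGCAGT
TGTATGAATAAATATGTGGCTGAAGAAGTATCTGGACCACAAACCTCAAGAGGCCCAGGC
>AS2UBAs2 synthetic novel new-group sequence
CCACAAACTTTCGGTCCCTCATGCCTGGGAATAGGCCTTCTACATGAGCGTCGGGCCATT
TCAGTCCATACTCGTGGCATCTGCAGTAACCCACTCGCTGTATTGTGGCCTTTCATGATC
TACAGTATGTTGGGACTTGACGACCTCTATACCATTCGACATTTATCGCTGCTGCCGGGA
AGGAGCGCTTTTGCCTCTCACGCGCATTATCTAAGTCGATCAAACTATTGCTATTGGGCT
TCTAATGTTATGCATACAGTAGGTTTCCGTACTAAGATATTCCGGTCACGCTGGTTCCCG
GCTGCGATGCTTAGAGGGTGCCCAAAGAAGGATTCTCATCTCAGAAACGCAGGCGTATAT
TGTGCTGTAATACAGTCCAAGGTAATGAATCGGCGTTGTGGCTTGTCAGACCTTCTGTGG
TTTTGCGTGAATCTAGTGTACCAATACAGACCGACTCGGGCACATTCCCGGGACAGCAGT
TGTATGAATAAATATGTGGCTGAAGAAGTATCTGGACCACAAACCTCAAGAGGCCCAGGC
>AS9UBAs2 synthetic novel new-group sequence
CCACAAACTTTCGGTCCCTCATGCCTGGGAATAGGCCTTCTACATGAGCGTCGGGCCATT
TCAGTCCATACTCGTGGCATCTGCAGTAACCCACTCGCTGTATTGTGGCCTTTCATGATC
TACAGTATGTTGGGACTTGACGACCTCTATACCATTCGACATTTATCGCTGCTGCCGGGA
AGGAGCGCTTTTGCCTCTCACGCGCATTATCTAAGTCGATCAAACTATTGCTATTGGGCT
TCTAATGTTATGCATACAGTAGGTTCTGGTGGGAACCTGGCCCGGTCACGCTGGTTCCCG
GCTGCGATGCTTAGAGGGACTTATTGGGAAAAAAGGCATCTCAGAAACGCAGGCGTATAT
TGTGCTGTAATACAGTCCAAGGTAATGAATCGGCGTTGTGGCTTGTCAGACCTTCTGTGG
TTTTGCGTGAATCTAGTGTACCAATACAGACCGACTCGGGCACATTCCCGGGACAGCAGT
TGTATGAATAAATATGTGGCTGAAGAAGTATCTGGACCACAAACCTCAAGAGGCCCAGGC
>AS5UBAs1 synthetic novel new-group, UBA1 primer site mutated sequence
CCACAAACTTTCGGTCCCTCATGCCTGGGAATAGACCTTCTACATGAGCGTCGGGCCATT
TCAGTCCATACTCGTGGCATCTGCAGTAACCCACTCGCTGTATTGTGGCCTTTCATGATC
TACAGTATGTTGGGACTTGACGACCTCTATACCATTCGACATTTATCGCTGCTGCCGGGA
AGGAGCGCTTTTGCCTCTCACGCGCATTATCTAAGTCGATCAAACTATTGCTATTGGGCT
TCTAATGTTATGCATACAGTAGGTTCTGGTGGGAACCTGGCCTACCAGTCATCCTATGTC
GCTGCGATGCTTAGAGGGTGCCCAAAGAAGGATTCTCATCTCAGAAACGCAGGCGTATAT
TGTGCTGTAATACAGTCCAAGGTAATGAATCGGCGTTGTGGCTTGTCAGACCTTCTGTGG
TTTTGCGTGAATCTAGTGTACCAATACAGACCGACTCGGGCACATTCCCGGGACAGCAGT
TGTATGAATAAATATGTGGCTGAAGAAGTATCTGGACCACAAACCTCAAGAGGCCCAGGC
>AS5UBAs2 synthetic novel new-group, UBA1 primer site mutated sequence
CCACAAACTTTCGGTCCCTCATGCCTGGGAATAGACCTTCTACATGAGCGTCGGGCCATT
TCAGTCCATACTCGTGGCATCTGCAGTAACCCACTCGCTGTATTGTGGCCTTTCATGATC
TACAGTATGTTGGGACTTGACGACCTCTATACCATTCGACATTTATCGCTGCTGCCGGGA
AGGAGCGCTTTTGCCTCTCACGCGCATTATCTAAGTCGATCAAACTATTGCTATTGGGCT
TCTAATGTTATGCATACAGTAGGTTCTGGTGGGAACCTGGCCCGGTCACGCTGGTTCCCG
CAATTCCATGACGGCCATTGCCCAAAGAAGGATTCTCATCTCAGAAACGCAGGCGTATAT
TGTGCTGTAATACAGTCCAAGGTAATGAATCGGCGTTGTGGCTTGTCAGACCTTCTGTGG
TTTTGCGTGAATCTAGTGTACCAATACAGACCGACTCGGGCACATTCCCGGGACAGCAGT
TGTATGAATAAATATGTGGCTGAAGAAGTATCTGGACCACAAACCTCAAGAGGCCCAGGC
>AS5DABs2 synthetic novel new-group sequence
ATGTCGATGTCTATCTTCTGCGCGGAAGACTATTGTACGGGCGGTTTCTGCGTTTCCCTG
ACCCGTGAGTTTGTTATAGAATTTCCTTTACCCCAATGCTCTGTAATTCTTTTCCTTGTG
CAAGTTGCTATTTGTAGGAGGGTTCATAATTGGGGATTCTTTTCATTCTTACCGATGTGT
GATTGTTGTTGGGGTTGCTCTTATTGGCTATGCAACTCCGATAATATCTACGCTAGTTTT
TTTGTTGAGAGTGCCGAATCGAAAAAACGCCGATACCGTATTGATCGCCGCCGAACCTTT
GCCAAAGGAAAATTCTCTACTAGCACCAGTTGGTGCCTAAGTTTCAGGAACTCTATTGCC
CTTGGAGATGACTTCGGGGCTTCACGTAACAACTCCATTAAAAAATTGTTTCATTACAGC
CATCCAAATAAAGCAAGCCGTAATATGCCTCGCTGCCCTCTAGAACTGGCTAACGGGGAC
TGGTACTGCCAATGCAATCCGATCCGGATT
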