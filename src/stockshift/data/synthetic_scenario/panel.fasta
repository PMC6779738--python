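>H01
AACCCTCTACCTGGTCCTGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H02
TCATCTCTACCTGGTCCTGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H03
TCCCGCCTACCTGGTCCTGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H04
TCCCCTGAACCTGGTCCTGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H05
TCCCCTCTGACTGGTCCTGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H06
TCCCCTCTACGGGGTCCTGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H07
TCCCCTCTACCTACTCCTGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H08
TCCCCTCTACCTGGAGCTGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H09
TCCCCTCTACCTGGTCAAGATCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H10
TCCCCTCTACCTGGTCCTCTTCGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H11
TCCCCTCTACCTGGTCCTGAAAGATACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
>H12
TCCCCTCTACCTGGTCCTGATCCTTACGGTATATGAGCTATTGGCGGTGCTTATCTCCCC
TTAATTTAACAGCCGTCCTGCTTTCATACGCAATTACACATCACCTACGAGGCGAAATAA
AGAGATTAATGCACAGTACTCATGGACTATCTTTGATATATGGGTACATCTCTTGCTTTT
GCTCCCTAAGCAATCGTCCAAGCTCCCACGTTCTTTCATTCAATCAGCAGCGATACGGAG
CTTGCGATTTAGGCGCTTACTAAACCGACCTGTGACGTTATTCTATTTAGCAGTTATCCG
TCGTCTTTATGCGCCCTTAGCGGGGGAGTTCTGCCTCATCGAAGAACCTCTGGAGATGTA
CCAAAGTGTTATCGGCGGGCTTAATAGCTATCGCTAGAGGTATCGGGTTAGGTTACATCT
ACCTTTCAGTGTGGCTGCAAAAAGGACGCCATACGACCTGAATGAATGCACCCC
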