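# synthetic data, stockshift generator v0.1.0, seed 20160101
# rookery baseline haplotype counts (9 stocks, 4 regions)
rookery,region,haplotype,count
R1,north-west,H06,128
R1,north-west,H10,35
R1,north-west,H11,3
R1,north-west,H12,34
R2,north-west,H01,42
R2,north-west,H04,4
R2,north-west,H06,2
R2,north-west,H07,13
R2,north-west,H08,1
R2,north-west,H11,8
R2,north-west,H12,130
R3,north-west,H02,2
R3,north-west,H03,9
R3,north-west,H04,9
R3,north-west,H06,31
R3,north-west,H08,10
R3,north-west,H10,29
R3,north-west,H11,5
R3,north-west,H12,105
R4,south-west,H03,6
R4,south-west,H04,104
R4,south-west,H05,45
R4,south-west,H07,3
R4,south-west,H09,27
R4,south-west,H10,15
R5,east,H02,1
R5,east,H03,136
R5,east,H04,3
R5,east,H05,6
R5,east,H06,13
R5,east,H07,16
R5,east,H08,1
R5,east,H11,18
R5,east,H12,6
R6,east,H01,2
R6,east,H03,6
R6,east,H06,110
R6,east,H10,79
R6,east,H11,2
R6,east,H12,1
R7,east,H02,105
R7,east,H04,6
R7,east,H05,14
R7,east,H06,18
R7,east,H07,54
R7,east,H10,3
R8,south-atlantic,H02,81
R8,south-atlantic,H03,1
R8,south-atlantic,H04,1
R8,south-atlantic,H05,8
R8,south-atlantic,H06,33
R8,south-atlantic,H07,53
R8,south-atlantic,H09,3
R8,south-atlantic,H10,15
R8,south-atlantic,H12,5
R9,south-atlantic,H01,31
R9,south-atlantic,H02,2
R9,south-atlantic,H04,1
R9,south-atlantic,H05,9
R9,south-atlantic,H06,40
R9,south-atlantic,H07,53
R9,south-atlantic,H08,1
R9,south-atlantic,H09,6
R9,south-atlantic,H10,30
R9,south-atlantic,H11,27
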