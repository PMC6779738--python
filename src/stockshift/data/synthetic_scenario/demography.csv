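# synthetic data, stockshift generator v0.1.0, seed 20160101
# stand-in demographic table for the synthetic scenario: regional Nr ranking
# constructed to match the true regional dC ranking; dC columns hold the true
# contribution changes (theta_late - theta_early), identical across size
# classes because the generator draws SCL independently of stock.
unit,region,N,D_km,r,Nr,dC_lt75,dC_lt50
north-west,-,29000,1630,0.138,4002,0.26,0.26
south-west,-,130000,1700,0.017,2210,-0.01,-0.01
east,-,22000,1010,0.064,1408,-0.22,-0.22
south-atlantic,-,46000,5990,0.035,1610,-0.03,-0.03
R1,north-west,18000,2140,0.140,2520,0.09,0.09
R2,north-west,5000,1430,0.180,900,0.09,0.09
R3,north-west,6000,1480,0.100,600,0.08,0.08
R4,south-west,130000,1700,0.017,2210,-0.01,-0.01
R5,east,3000,540,0.080,240,-0.08,-0.08
R6,east,13000,1510,0.040,520,-0.08,-0.08
R7,east,6000,1760,0.050,300,-0.06,-0.06
R8,south-atlantic,29000,5850,0.035,1015,-0.02,-0.02
R9,south-atlantic,17000,6160,0.035,595,-0.01,-0.01
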