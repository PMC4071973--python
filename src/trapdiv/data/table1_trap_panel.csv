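primer_combination,total_bands,polymorphic_bands,pct_polymorphism,pic,mi,size_range
EF69R1-EM10,12,9,75.00,0.50,5.94,100-2000
EU94L1-EM9,12,5,41.67,0.50,5.96,150-1900
GQ76R1-EM1,8,4,50.00,0.46,3.70,300-1100
GQ76R1-EM2,8,3,37.50,0.38,3.05,170-1200
GQ76R1-EM4,6,4,66.67,0.50,3.00,150-2100
GQ76R1-EM5,11,7,63.64,0.49,5.38,100-1200
GQ76R1-EM6,9,6,66.67,0.50,4.46,100-750
GQ76R1-EM17,17,11,64.71,0.50,8.50,120-2100
GQ76R1-ME1,13,10,76.92,0.49,6.38,250-2000
GQ76R1-ME2,12,7,58.33,0.50,5.99,150-1700
GQ76R1-ME4,14,11,78.57,0.48,6.72,150-1900
GQ76R1-ME7,10,4,40.00,0.48,4.84,120-1800
GQ76R1-ME8,5,3,60.00,0.49,2.46,300-1200
GQ76R1-ME9,7,6,85.71,0.39,2.75,150-1200
GQ76R1-ME11,13,9,69.23,0.50,6.48,150-1800
GQ76R1-ME13,11,7,63.64,0.48,5.28,120-1700
JN00L1-EM5,16,13,81.25,0.50,7.99,100-1600
JN00L1-EM10,14,10,71.43,0.50,6.99,200-900
JN00L1-EM16,10,8,77.78,0.50,4.48,100-900
JN00L1-EM26,10,8,80.00,0.50,5.00,120-1000
JN00L1-ME6,4,2,75.00,0.50,2.00,150-500
JN00L1-ME11,6,2,33.33,0.32,1.92,150-500
JN00R1-EM2,13,11,84.62,0.49,6.41,120-1700
JN00R1-EM6,10,9,90.00,0.45,4.52,200-700
JN00R1-EM24,9,8,88.89,0.46,4.15,150-1000
JN00R1-ME2,11,9,81.82,0.50,5.45,100-1200
JN00R1-ME4,10,9,90.00,0.49,4.94,100-1100
JN00R1-ME6,7,7,100.00,0.50,3.49,300-1500
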