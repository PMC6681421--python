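residue,name,q00,dq00,T,dT,group
A,Alanine,0.5506,0,98288.00,0,A
C,Cysteine,0.5481,0.0024,98302.46,14.46,B
D,Aspartate,0.5604,0.0098,98309.59,21.59,D
E,Glutamate,0.5461,0.0045,98306.89,18.89,B
F,Phenylalanine,0.5556,0.0049,98292.99,4.99,A
G,Glycine,0.5562,0.0048,98295.42,7.41,A
H,Histidine,0.5609,0.0103,98303.85,15.85,D
I,Isoleucine,0.5546,0.0040,98296.09,8.09,A
K,Lysine,0.5416,0.0090,98299.67,11.66,D
L,Leucine,0.5456,0.0049,98301.49,13.49,B
M,Methionine,0.5491,0.0015,98320.71,32.71,B
N,Asparagine,0.5570,0.0064,98285.68,2.32,C
P,Proline,0.5450,0.0055,98332.57,44.57,E
Q,Glutamine,0.5439,0.0067,98293.09,5.08,C
R,Arginine,0.5429,0.0077,98293.44,5.44,C
S,Serine,0.5479,0.0027,98312.53,24.53,B
T,Threonine,0.5500,0.0006,98311.72,23.71,B
V,Valine,0.5525,0.0019,98297.51,9.51,A
W,Tryptophan,0.5650,0.0145,98300.29,12.29,D
Y,Tyrosine,0.5429,0.0077,98312.98,24.98,D
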