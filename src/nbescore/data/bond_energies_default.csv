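# Default bond-energy table: standard average bond enthalpies at 298 K (kJ/mol),
# transcribed from common physical-chemistry reference tables.
# Orders: 1 = single, 2 = double, 3 = triple. Lookup is symmetric in the two elements.
element_a,element_b,order,energy_kj_mol
H,H,1,436
H,F,1,567
H,Cl,1,431
H,Br,1,366
H,I,1,299
C,H,1,413
C,C,1,347
C,C,2,614
C,C,3,839
C,N,1,305
C,N,2,615
C,N,3,891
C,O,1,358
C,O,2,745
C,O,3,1072
C,F,1,485
C,Cl,1,339
C,Br,1,276
C,I,1,240
C,S,1,259
C,S,2,573
C,P,1,264
C,Si,1,301
N,H,1,391
N,N,1,163
N,N,2,418
N,N,3,941
N,O,1,201
N,O,2,607
N,F,1,272
N,Cl,1,200
O,H,1,467
O,O,1,146
O,O,2,495
O,F,1,190
O,Si,1,452
F,F,1,154
Cl,Cl,1,243
Br,Br,1,193
I,I,1,151
Br,Cl,1,218
I,Cl,1,208
I,Br,1,175
S,H,1,347
S,S,1,266
S,S,2,418
S,F,1,327
S,Cl,1,253
S,O,1,265
S,O,2,522
P,H,1,322
P,P,1,201
P,O,1,335
P,O,2,544
P,F,1,490
P,Cl,1,326
P,Br,1,264
Si,H,1,318
Si,Si,1,222
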