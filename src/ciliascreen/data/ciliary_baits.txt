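# 41 C. elegans genes with established ciliary roles, used as correlation
# baits (sequence-name IDs; must match the ID scheme of the expression table)
R148.1
F38G1.1
Y75B8A.12
F20D12.3
Y41G9A.1
R01H10.6
C54G7.4
C27A7.4
R31.3
C48B6.8
F32A6.2
C27H5.7
T28F3.6
Y37E3.5
F59C6.7
F19H8.3
ZC84.2
F35D2.4
H01G02.2
B0240.3
ZK520.3
C02H7.1
ZK418.3
K08D12.2
F23B2.4
Y105E8A.5
F46F6.4
K07G5.3
F33H1.1
F02D8.3
K03E6.4
C38D4.8
T26C12.4
T27B1.1
Y110A7A.20
F53A9.4
M04C9.5
C30B5.9
C09G5.8
R13H4.1
F54C1.5
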