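# Scenario-1 reference cell: T_S = T_I = T_O = 1e5 generations, 2N = 1e4
# gene copies, P1 accelerated by 50%, no introgression.
TS: 1.0e5
TI: 1.0e5
TO: 1.0e5
twoN: 1.0e4
lambdaP1: 1.5
lambdaP3: 1.0
lambdaO: 1.0
gamma: 0.0
TG: 0.0
GS: 10000000
locus_length: 100
mu: 2.0e-8
reps: 20
seed: 1
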