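# Published 30-run central composite inscribed design (4 factors, alpha=2,
# 6 centre runs) with observed Kocuria sp. RAM1 carotenoid yield (ug/ml)
# and the published predicted column of the reported quadratic model.
run,peptone,temperature,agitation,inoculum_size,response,predicted
1,0,0,2,0,800.0,773.1
2,0,0,0,0,380.06,509.25
3,-1,-1,-1,-1,575.1,580.38
4,-1,1,-1,-1,376.0,330.46
5,-2,0,0,0,222.18,239.28
6,1,1,-1,-1,218.46,261.83
7,1,-1,-1,-1,547.88,611.47
8,1,1,1,1,366.12,429.13
9,0,0,0,0,555.74,509.25
10,-1,-1,1,1,597.46,622.38
11,-1,1,1,1,378.72,264.98
12,0,0,0,0,534.92,509.25
13,0,0,0,0,555.52,509.25
14,1,-1,1,1,890.86,886.25
15,0,2,0,0,137.32,91.5
16,1,1,-1,1,316.34,284.33
17,-1,-1,-1,1,519.1,462.26
18,1,1,1,-1,398.66,405.35
19,0,0,0,0,495.28,509.25
20,0,0,0,-2,711.6,636.14
21,1,-1,-1,1,667.4,618.92
22,-1,1,-1,1,156.14,227.38
23,0,0,0,2,484.46,541.79
24,1,-1,1,-1,880.46,877.51
25,0,0,0,0,534.0,509.25
26,-1,-1,1,-1,757.38,739.23
27,0,0,-2,0,460.68,469.45
28,2,0,0,0,469.74,434.51
29,0,-2,0,0,770.86,798.55
30,-1,1,1,-1,250.0,366.77
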