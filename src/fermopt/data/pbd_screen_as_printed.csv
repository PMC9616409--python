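# Published 12-run Plackett-Burman screen of 11 culture factors for
# Kocuria sp. RAM1 carotenoid yield (ug/ml), coded -1/+1 levels, with the
# published predicted column of the reported first-order model.
# Observed values exactly as published (run 12 = 158.900).
run,peptone,yeast_extract,beef_extract,nacl,glucose,mgso4,ph,temperature,agitation,inoculum_size,incubation_period,response,predicted
1,1,1,1,-1,-1,-1,-1,-1,1,1,1,409.871,407.92
2,-1,1,1,-1,-1,1,1,1,1,-1,-1,119.234,103.15
3,-1,1,1,1,1,1,-1,-1,-1,-1,1,128.0,136.39
4,1,-1,1,1,1,-1,-1,1,1,-1,-1,146.43,162.78
5,1,-1,-1,-1,1,1,1,-1,1,-1,1,350.0,333.86
6,-1,-1,-1,1,-1,1,-1,1,1,1,1,139.12,177.22
7,1,1,-1,-1,1,1,-1,1,-1,1,-1,115.936,99.0
8,1,1,-1,1,-1,-1,1,1,-1,-1,1,26.83,24.93
9,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,127.0,136.39
10,-1,1,-1,1,1,-1,1,-1,1,1,-1,368.567,348.3
11,1,-1,1,1,-1,1,1,-1,-1,1,-1,249.5,270.08
12,-1,-1,1,-1,1,-1,1,1,-1,1,1,158.9,39.37
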