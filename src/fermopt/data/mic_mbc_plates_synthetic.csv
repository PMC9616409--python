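# SYNTHETIC reconstruction of broth-microdilution growth flags: only the
# MIC/MBC endpoints were published; well-by-well flags here are the unique
# monotone pattern consistent with those endpoints on a 2-fold series.
pathogen,concentration,broth_growth,subculture_growth
Staphylococcus aureus ATCC 25923,62.5,True,True
Staphylococcus aureus ATCC 25923,125,False,True
Staphylococcus aureus ATCC 25923,250,False,True
Staphylococcus aureus ATCC 25923,500,False,True
Staphylococcus aureus ATCC 25923,1000,False,False
Bacillus subtilis ATCC 6633,62.5,True,True
Bacillus subtilis ATCC 6633,125,False,True
Bacillus subtilis ATCC 6633,250,False,True
Bacillus subtilis ATCC 6633,500,False,True
Bacillus subtilis ATCC 6633,1000,False,True
Enterococcus faecalis ATCC 29212,62.5,True,True
Enterococcus faecalis ATCC 29212,125,True,True
Enterococcus faecalis ATCC 29212,250,True,True
Enterococcus faecalis ATCC 29212,500,False,True
Enterococcus faecalis ATCC 29212,1000,False,True
Escherichia coli ATCC 8739,62.5,True,True
Escherichia coli ATCC 8739,125,True,True
Escherichia coli ATCC 8739,250,True,True
Escherichia coli ATCC 8739,500,False,True
Escherichia coli ATCC 8739,1000,False,False
Pseudomonas aeruginosa ATCC 9027,62.5,True,True
Pseudomonas aeruginosa ATCC 9027,125,True,True
Pseudomonas aeruginosa ATCC 9027,250,True,True
Pseudomonas aeruginosa ATCC 9027,500,False,True
Pseudomonas aeruginosa ATCC 9027,1000,False,True
Klebsiella pneumoniae ATCC 13883,62.5,True,True
Klebsiella pneumoniae ATCC 13883,125,True,True
Klebsiella pneumoniae ATCC 13883,250,True,True
Klebsiella pneumoniae ATCC 13883,500,False,True
Klebsiella pneumoniae ATCC 13883,1000,False,False
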