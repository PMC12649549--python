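peptide,hc10_ug_ml,censored
W5K/A9W,30.0,False
W5K01,70.9,False
W5K02,16.7,False
W5K03,108.7,True
W5K04,108.7,True
W5K05,108.7,True
W5K06,108.7,True
W5K07,108.7,True
W5K08,108.7,True
W5K09,108.7,True
W5K10,108.7,True
W5K11,71.0,False
W5K12,41.7,False
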