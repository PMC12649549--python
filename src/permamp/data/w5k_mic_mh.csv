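strain,gram,W5K/A9W,W5K01,W5K02,W5K03,W5K04,W5K05,W5K06,W5K07,W5K08,W5K09,W5K10,W5K11,W5K12
E. coli ATCC 25922,negative,3.13,12.5,12.5,50,25,12.5,25,50,50,25,6.25,6.25,3.13
P. aeruginosa ATCC 27853,negative,3.13,12.5,25,50,50,25,50,50,25,25,6.25,3.13,3.13
A. baumannii 14B0091,negative,1.56,6.25,3.13,6.25,12.5,12.5,50,12.5,>50,50,1.56,0.78,1.56
A. baumannii 14B0097,negative,1.56,6.25,3.13,6.25,12.5,6.25,50,12.5,25,25,1.56,1.56,1.56
A. baumannii 14B00100,negative,1.56,6.25,6.25,12.5,12.5,12.5,50,12.5,>50,50,3.13,1.56,3.13
S. aureus ATCC 25923,positive,3.13,12.5,25,50,50,25,50,50,25,25,6.25,3.13,3.13
S. aureus ATCC 33591,positive,12.5,50,25,>50,>50,50,>50,>50,>50,>50,12.5,12.5,6.25
S. aureus ATCC 33592,positive,12.5,50,25,>50,>50,50,>50,>50,>50,>50,12.5,6.25,6.25
S. aureus ATCC 33593,positive,12.5,50,25,>50,>50,50,>50,>50,>50,>50,12.5,6.25,6.25
S. aureus ATCC 6538,positive,6.25,12.5,12.5,25,25,12.5,50,>50,>50,>50,6.25,3.13,3.13
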