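year,ptb_pct,live_birth_change_pct,ptb_change_pct
2013,5.75,,
2014,5.41,2.80,-3.32
2015,5.31,-0.37,-2.34
2016,5.53,0.83,5.06
2017,5.50,-2.64,-3.17
2018,5.34,1.78,-1.23
2019,5.53,0.60,4.33
2020,5.17,6.16,-0.71
2021,5.36,5.34,9.05
2022,5.77,-8.41,-1.31
2023,6.85,-4.57,13.27
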