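year,observed,predicted,absolute_error
2019,22172,22170,2
2020,22014,22010,4
2021,24005,24000,5
2022,23692,23690,2
2023,26837,26830,7
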