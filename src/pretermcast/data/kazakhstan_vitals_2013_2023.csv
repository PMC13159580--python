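year,live_births,preterm_births
2013,389150,22401
2014,400047,21657
2015,398584,21150
2016,401886,22221
2017,391281,21516
2018,398249,21252
2019,400653,22172
2020,425326,22014
2021,448055,24005
2022,410348,23692
2023,391562,26837
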