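period,value
2007,24.681
2008,23.212
2009,22.144
2010,21.851
2011,22.179
2012,21.176
2013,20.44
2014,19.744
2015,18.591
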