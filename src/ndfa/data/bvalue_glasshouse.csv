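landrace,organ,delta15n,n_content_mg
Puffeun,shoot,-3.68,
Puffeun,root,-2.60,
Funsi,shoot,-3.99,
Funsi,root,-3.31,
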