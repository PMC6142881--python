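site,species,delta15n
Nyankpala,Ageratum conyzoides,3.85
Nyankpala,Brachiaria lata,5.08
Nyankpala,Chloris pilosa,4.12
Nyankpala,Corchorus olitorius,3.98
Nyankpala,Cynodon dactylon,2.93
Nyankpala,Hyptis suaveolens,3.50
Nyankpala,Ludwigia abyssinica,3.66
Nyankpala,Ludwigia decurrens,3.77
Nyankpala,Paspalum scrobiculatum,4.66
Savelugu,Ageratum conyzoides,3.53
Savelugu,Brachiaria lata,4.18
Savelugu,Chloris pilosa,3.54
Savelugu,Corchorus olitorius,1.37
Savelugu,Cynodon dactylon,2.48
Savelugu,Hyptis suaveolens,3.43
Savelugu,Ludwigia abyssinica,3.42
Savelugu,Ludwigia decurrens,3.34
Savelugu,Paspalum scrobiculatum,2.09
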