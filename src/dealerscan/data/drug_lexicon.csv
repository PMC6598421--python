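drug,hashtag,category
xanax,xanax,drug_name
xanax,zanax,codeword_misspelling
xanax,2mgxanax,codeword_extended
xanax,greenxanax,codeword_extended
xanax,xanaxfamily,codeword_extended
xanax,whitebar,codeword_street
oxycodone,oxycodone,drug_name
oxycodone,oxycontin,drug_name
oxycodone,oxycodine,codeword_misspelling
oxycodone,oxicotin,codeword_misspelling
oxycodone,oxicodone,codeword_misspelling
oxycodone,oxy80s,codeword_extended
lsd,lsd25,codeword_extended
lsd,lsdtabs,codeword_extended
mdma,mdmapills,codeword_extended
mdma,mdmaforsale,codeword_extended
mdma,mdmazing,codeword_street
mdma,mdmaonline,codeword_extended
sale,forsale,sale_or_shipping
sale,shipping,sale_or_shipping
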