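xanax
zanax
xan
whitebar
oxy
oxi
percocet
percocert
adderall
adderrall
hydrocodone
codeine
fentanyl
lsd
acid
mdma
molly
ecstasy
opioid
pill
painkiller
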