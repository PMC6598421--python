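how much
price
what does it cost
want to buy
wanna buy
can i order
can i buy
can i get
how do i order
how do i get
i'll take
ill take
still available
interested in buying
dm me the price
send me the price
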