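# CRP binding-site consensus: palindromic pentamer half-sites, 6-bp spacer
TGTGANNNNNNTCACA
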