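clade,label,rollup
bivalve,epibyssate,epifaunal
bivalve,cemented,epifaunal
bivalve,reclining,epifaunal
bivalve,shallow_infaunal,infaunal
bivalve,deep_infaunal,infaunal
bivalve,unknown,unknown
brachiopod,pedicle_attached,epifaunal
brachiopod,cemented,epifaunal
brachiopod,reclining,epifaunal
brachiopod,infaunal,infaunal
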