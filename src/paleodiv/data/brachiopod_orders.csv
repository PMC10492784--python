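order,lifestyle,pt_group
Spiriferida,pedicle_attached,PT_e
Productida,reclining,PT_e
Orthotetida,cemented,PT_e
Orthida,pedicle_attached,PT_e
Dictyonellida,pedicle_attached,PT_e
Lingulida,infaunal,PT_s
Terebratulida,pedicle_attached,PT_s
Athyridida,pedicle_attached,PT_s
Rhynchonellida,pedicle_attached,PT_s
Spiriferinida,pedicle_attached,PT_s
Craniida,cemented,PT_s
Thecideida,cemented,PT_s
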