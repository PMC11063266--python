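# Default dimensionless risk coefficients per tissue class.  The ordering
# follows qualitative severity: brainstem retraction carries respiratory or
# circulatory risk (highest); arteries and cranial nerves rank next (ischemia,
# palsies); venous injury is troublesome but often tolerated; cerebellar
# retraction and bone removal are routine costs.  Free space is 0 by
# definition.  Override any entry with --coeffs / load_coefficients.
space: 0
bone: 1
cerebellum: 2
vein: 3
artery: 4
cranial_nerve: 4
brainstem: 5
other: 1
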