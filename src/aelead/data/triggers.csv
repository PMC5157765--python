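kind,phrase
hearsay,my friend
hearsay,a friend of mine
hearsay,my mother
hearsay,my father
hearsay,my husband
hearsay,my wife
hearsay,my sister
hearsay,my brother
hearsay,my coworker
hearsay,i read that
hearsay,i heard
hearsay,heard that
hearsay,someone told me
hearsay,people say
serious,hospital
serious,emergency room
serious,life-threatening
serious,life threatening
serious,died
serious,death
serious,passed away
serious,disability
serious,disabled
serious,permanent damage
serious,permanent impairment
serious,intensive care
serious,almost lost my life
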