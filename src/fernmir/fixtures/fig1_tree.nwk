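(liverworts,(mosses,(lycophytes,(ferns,(gymnosperms,(basal_angiosperms,(monocots,eudicots)core_angiosperms)angiospermae)spermatophyta)euphyllophyta)tracheophyta)moss_vascular)embryophyta;
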