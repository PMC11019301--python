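# Known single-substitution spectral effects at SWS1 tuning sites (bovine rhodopsin
# numbering). Reverse substitutions apply with flipped sign. Overridable via config.
site	from	to	delta_nm	provenance
118	A	S	5.0	A118S known to blue->red shift SWS1 lambda_max by +5 nm (site-directed mutagenesis literature)
114	A	S	5.0	package default: reproduces the ~10 nm joint short/long shift and lies inside the 3-9 nm single-site interval reported for Chromis SWS1 duplicates; not an empirically measured value
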