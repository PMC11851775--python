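design_id	dope	fastrelax
i1	1731	-196
i2	1737	-205
i3	1800	-177
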