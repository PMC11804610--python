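# SYNTHETIC stand-in registry of the 19 HG structures reported before this
# screen. The authoritative list is a supplementary table not bundled here;
# entries below are the canonical hexose/pentose HGs of the cited earlier
# literature, chosen to match the published registry size of 19.
headgroup	chain	pattern
hexose	26	diol
hexose	26	keto-ol
hexose	28	diol
hexose	28	keto-ol
hexose	28	keto-diol
hexose	28	triol
hexose	30	diol
hexose	30	keto-ol
hexose	30	keto-diol
hexose	30	triol
hexose	32	diol
hexose	32	keto-diol
hexose	32	triol
pentose	26	diol
pentose	26	keto-ol
pentose	28	keto-diol
pentose	28	triol
pentose	30	keto-diol
pentose	30	triol
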