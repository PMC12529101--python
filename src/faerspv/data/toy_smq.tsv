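smq	pt	scope
Oropharyngeal conditions	Mouth ulceration	narrow
Oropharyngeal conditions	Aphthous ulcer	narrow
Oropharyngeal conditions	Nasopharyngitis	broad
Gastrointestinal ulceration	Mouth ulceration	narrow
Gastrointestinal ulceration	Aphthous ulcer	broad
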