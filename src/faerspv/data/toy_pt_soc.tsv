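pt	soc
Acne	Skin and subcutaneous tissue disorders
Folliculitis	Skin and subcutaneous tissue disorders
Rash	Skin and subcutaneous tissue disorders
Mouth ulceration	Gastrointestinal disorders
Aphthous ulcer	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Nasopharyngitis	Infections and infestations
Pneumonia	Infections and infestations
Urinary tract infection	Infections and infestations
Arthralgia	Musculoskeletal and connective tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
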