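# Study configuration: synthetic psoriasis/PsA reporting corpus with
# implanted drug-event associations mimicking the safety profiles under
# study (dermatologic signals for deucravacitinib, musculoskeletal and
# infection signals for upadacitinib/tofacitinib).
out_dir: results/study
seed: 20240901
synth:
  n_cases: 20000
  seed: 20240901
  theta:
    deucravacitinib|Acne: 6.0
    deucravacitinib|Folliculitis: 5.0
    deucravacitinib|Mouth ulceration: 4.0
    deucravacitinib|Aphthous ulcer: 3.5
    upadacitinib|Arthralgia: 3.0
    upadacitinib|Back pain: 2.5
    upadacitinib|Pneumonia: 2.2
    tofacitinib|Herpes zoster: 2.5
    tofacitinib|Back pain: 2.8
    tofacitinib|Nausea: 1.8
levels: [PT, SOC, SMQ]
subgroups: [all, psoriasis, psa]
ic_method: approx
sensitivity_socs:
  - Skin and subcutaneous tissue disorders
  - Infections and infestations
  - Gastrointestinal disorders
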