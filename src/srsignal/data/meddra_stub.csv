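pt,pt_code,soc,soc_code
Myalgia,10028411,Musculoskeletal and connective tissue disorders,10028395
Blood creatine phosphokinase increased,10005470,Investigations,10022891
Blood creatinine increased,10005483,Investigations,10022891
Blood creatine increased,10005464,Investigations,10022891
Muscle fatigue,10049565,Musculoskeletal and connective tissue disorders,10028395
Pain in extremity,10033425,Musculoskeletal and connective tissue disorders,10028395
Arthralgia,10003239,Musculoskeletal and connective tissue disorders,10028395
Headache,10019211,Nervous system disorders,10029205
Gout,10018627,Metabolism and nutrition disorders,10027433
Hypoglycaemia,10020993,Metabolism and nutrition disorders,10027433
Prothrombin time prolonged,10037063,Investigations,10022891
Photosensitivity reaction,10034972,Skin and subcutaneous tissue disorders,10040785
Rash,10037844,Skin and subcutaneous tissue disorders,10040785
Rhabdomyolysis,10039020,Musculoskeletal and connective tissue disorders,10028395
Renal impairment,10062237,Renal and urinary disorders,10038359
Renal failure,10038435,Renal and urinary disorders,10038359
Hepatitis,10019717,Hepatobiliary disorders,10019805
Hepatic enzyme increased,10060795,Investigations,10022891
Cholelithiasis,10008629,Hepatobiliary disorders,10019805
Pancreatitis,10033645,Gastrointestinal disorders,10017947
Dyspepsia,10013946,Gastrointestinal disorders,10017947
Nausea,10028813,Gastrointestinal disorders,10017947
Vomiting,10047700,Gastrointestinal disorders,10017947
Diarrhoea,10012735,Gastrointestinal disorders,10017947
Abdominal pain,10000081,Gastrointestinal disorders,10017947
Constipation,10010774,Gastrointestinal disorders,10017947
Fatigue,10016256,General disorders and administration site conditions,10018065
Asthenia,10003549,General disorders and administration site conditions,10018065
Dizziness,10013573,Nervous system disorders,10029205
Pruritus,10037087,Skin and subcutaneous tissue disorders,10040785
Urticaria,10046735,Skin and subcutaneous tissue disorders,10040785
Anaemia,10002034,Blood and lymphatic system disorders,10005329
Muscle spasms,10028334,Musculoskeletal and connective tissue disorders,10028395
Eye opacity,10015925,Eye disorders,10015919
Vision blurred,10047513,Eye disorders,10015919
Chest pain,10008479,General disorders and administration site conditions,10018065
Dyspnoea,10013968,"Respiratory, thoracic and mediastinal disorders",10038738
Cough,10011224,"Respiratory, thoracic and mediastinal disorders",10038738
Insomnia,10022437,Psychiatric disorders,10037175
Anxiety,10002855,Psychiatric disorders,10037175
Depression,10012378,Psychiatric disorders,10037175
Hypertension,10020772,Vascular disorders,10047065
Palpitations,10033557,Cardiac disorders,10007541
Oedema peripheral,10030124,General disorders and administration site conditions,10018065
Weight decreased,10047895,Investigations,10022891
Weight increased,10047899,Investigations,10022891
Decreased appetite,10061428,Metabolism and nutrition disorders,10027433
Pyrexia,10037660,General disorders and administration site conditions,10018065
Malaise,10025482,General disorders and administration site conditions,10018065
Back pain,10003988,Musculoskeletal and connective tissue disorders,10028395
Hyperhidrosis,10020642,Skin and subcutaneous tissue disorders,10040785
Alopecia,10001760,Skin and subcutaneous tissue disorders,10040785
Dry mouth,10013781,Gastrointestinal disorders,10017947
Somnolence,10041349,Nervous system disorders,10029205
Tremor,10044565,Nervous system disorders,10029205
Paraesthesia,10033775,Nervous system disorders,10029205
Tinnitus,10043882,Ear and labyrinth disorders,10013993
Vertigo,10047340,Ear and labyrinth disorders,10013993
Epistaxis,10015090,"Respiratory, thoracic and mediastinal disorders",10038738
Flushing,10016825,Vascular disorders,10047065
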