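pt,soc
Dyskinesia,Nervous system disorders
Tardive dyskinesia,Nervous system disorders
Dystonia,Nervous system disorders
Hyperkinesia,Nervous system disorders
Ballismus,Nervous system disorders
Alien limb syndrome,Nervous system disorders
On and off phenomenon,Nervous system disorders
Freezing phenomenon,Nervous system disorders
Parkinson's disease,Nervous system disorders
Parkinsonism,Nervous system disorders
Tremor,Nervous system disorders
Bradykinesia,Nervous system disorders
Akinesia,Nervous system disorders
Dizziness,Nervous system disorders
Headache,Nervous system disorders
Somnolence,Nervous system disorders
Syncope,Nervous system disorders
Seizure,Nervous system disorders
Memory impairment,Nervous system disorders
Paraesthesia,Nervous system disorders
Hypoaesthesia,Nervous system disorders
Polyneuropathy,Nervous system disorders
Fatigue,General disorders and administration site conditions
Asthenia,General disorders and administration site conditions
Malaise,General disorders and administration site conditions
Gait disturbance,General disorders and administration site conditions
Therapeutic response shortened,General disorders and administration site conditions
Therapeutic response incomplete,General disorders and administration site conditions
Therapeutic response decreased,General disorders and administration site conditions
Drug ineffective,General disorders and administration site conditions
Oedema peripheral,General disorders and administration site conditions
Pyrexia,General disorders and administration site conditions
Death,General disorders and administration site conditions
Condition aggravated,General disorders and administration site conditions
Feeling abnormal,General disorders and administration site conditions
Mobility decreased,General disorders and administration site conditions
Dementia,Psychiatric disorders
Hallucination,Psychiatric disorders
Hallucination visual,Psychiatric disorders
Psychotic disorder,Psychiatric disorders
Delusion,Psychiatric disorders
Confusional state,Psychiatric disorders
Insomnia,Psychiatric disorders
Anxiety,Psychiatric disorders
Depression,Psychiatric disorders
Impulse-control disorder,Psychiatric disorders
Agitation,Psychiatric disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Constipation,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Dry mouth,Gastrointestinal disorders
Abdominal pain,Gastrointestinal disorders
Rash,Skin and subcutaneous tissue disorders
Pruritus,Skin and subcutaneous tissue disorders
Hyperhidrosis,Skin and subcutaneous tissue disorders
Hypertension,Vascular disorders
Hypotension,Vascular disorders
Orthostatic hypotension,Vascular disorders
Palpitations,Cardiac disorders
Fall,"Injury, poisoning and procedural complications"
Contusion,"Injury, poisoning and procedural complications"
Weight decreased,Investigations
Blood pressure decreased,Investigations
Muscle rigidity,Musculoskeletal and connective tissue disorders
Muscular weakness,Musculoskeletal and connective tissue disorders
Arthralgia,Musculoskeletal and connective tissue disorders
Back pain,Musculoskeletal and connective tissue disorders
Muscle spasms,Musculoskeletal and connective tissue disorders
Dyspnoea,"Respiratory, thoracic and mediastinal disorders"
Decreased appetite,Metabolism and nutrition disorders
Vision blurred,Eye disorders
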