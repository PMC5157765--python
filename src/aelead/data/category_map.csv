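sm_category,reg_category
Muscle or bone pain,Muscle pains
Muscle or joint pain,Muscle pains
Joint pain,Joint related signs and symptoms
Cramps,Muscle related signs and symptoms NEC
Weakness,Muscle weakness conditions
Low energy,Asthenic conditions
Headache,Headaches NEC
Headaches,Headaches NEC
Insomnia,Disturbances in initiating and maintaining sleep
Anxiety,Anxiety symptoms
Anxiety or irritability,Anxiety symptoms
Depression,Depressive disorders
Mental fog or memory loss,Memory loss (excl dementia)
Numbness,Paraesthesias and dysaesthesias
Vertigo,Neurological signs and symptoms NEC
Heart issue or chest pain,Cardiac signs and symptoms NEC
Cardiac symptoms,Cardiac signs and symptoms NEC
Hypertension,Vascular tests NEC (incl blood pressure)
Dry mouth,Oral dryness and saliva altered
Nausea or indigestion,Nausea and vomiting symptoms
Constipation,Gastrointestinal atonic and hypomotility disorders NEC
Stomach or bowel issues,Gastrointestinal and abdominal pains
Swelling,Oedema NEC
Lack of efficacy,Therapeutic and nontherapeutic responses
Shortness of breath,Breathing abnormalities
Sexual dysfunction,Sexual desire disorders
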