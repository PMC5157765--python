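pt,hlt,hlgt,soc
myalgia,Muscle pains,Musculoskeletal and connective tissue disorders NEC,Musculoskeletal and connective tissue disorders
muscle fatigue,Muscle pains,Musculoskeletal and connective tissue disorders NEC,Musculoskeletal and connective tissue disorders
musculoskeletal pain,Musculoskeletal and connective tissue pain and discomfort,Musculoskeletal and connective tissue disorders NEC,Musculoskeletal and connective tissue disorders
musculoskeletal discomfort,Musculoskeletal and connective tissue pain and discomfort,Musculoskeletal and connective tissue disorders NEC,Musculoskeletal and connective tissue disorders
back pain,Musculoskeletal and connective tissue pain and discomfort,Musculoskeletal and connective tissue disorders NEC,Musculoskeletal and connective tissue disorders
arthralgia,Joint related signs and symptoms,Joint disorders,Musculoskeletal and connective tissue disorders
joint stiffness,Joint related signs and symptoms,Joint disorders,Musculoskeletal and connective tissue disorders
muscle spasms,Muscle related signs and symptoms NEC,Muscle disorders,Musculoskeletal and connective tissue disorders
muscle twitching,Muscle related signs and symptoms NEC,Muscle disorders,Musculoskeletal and connective tissue disorders
rhabdomyolysis,Myopathies,Muscle disorders,Musculoskeletal and connective tissue disorders
myopathy,Myopathies,Muscle disorders,Musculoskeletal and connective tissue disorders
muscle necrosis,Myopathies,Muscle disorders,Musculoskeletal and connective tissue disorders
muscular weakness,Muscle weakness conditions,Muscle disorders,Musculoskeletal and connective tissue disorders
palpitations,Cardiac signs and symptoms NEC,Cardiac disorder signs and symptoms,Cardiac disorders
tachycardia,Rate and rhythm disorders NEC,Cardiac arrhythmias,Cardiac disorders
arrhythmia,Rate and rhythm disorders NEC,Cardiac arrhythmias,Cardiac disorders
myocardial infarction,Ischaemic coronary artery disorders,Coronary artery disorders,Cardiac disorders
angina pectoris,Ischaemic coronary artery disorders,Coronary artery disorders,Cardiac disorders
hypertension,Vascular hypertensive disorders,Blood pressure disorders,Vascular disorders
hypotension,Vascular hypotensive disorders,Blood pressure disorders,Vascular disorders
cerebrovascular accident,Central nervous system haemorrhages and cerebrovascular accidents,Cerebrovascular disorders,Vascular disorders
transient ischaemic attack,Central nervous system haemorrhages and cerebrovascular accidents,Cerebrovascular disorders,Vascular disorders
headache,Headaches NEC,Headaches,Nervous system disorders
migraine,Headaches NEC,Headaches,Nervous system disorders
dizziness,Neurological signs and symptoms NEC,Neurological disorders NEC,Nervous system disorders
paraesthesia,Paraesthesias and dysaesthesias,Neurological disorders NEC,Nervous system disorders
hypoaesthesia,Paraesthesias and dysaesthesias,Neurological disorders NEC,Nervous system disorders
memory impairment,Memory loss (excl dementia),Mental impairment disorders,Nervous system disorders
amnesia,Memory loss (excl dementia),Mental impairment disorders,Nervous system disorders
gait disturbance,Gait disturbances,Neurological disorders NEC,Nervous system disorders
loss of consciousness,Disturbances in consciousness NEC,Neurological disorders NEC,Nervous system disorders
syncope,Disturbances in consciousness NEC,Neurological disorders NEC,Nervous system disorders
insomnia,Disturbances in initiating and maintaining sleep,Sleep disorders and disturbances,Psychiatric disorders
anxiety,Anxiety symptoms,Anxiety disorders and symptoms,Psychiatric disorders
depression,Depressive disorders,Depressed mood disorders and disturbances,Psychiatric disorders
depressed mood,Depressive disorders,Depressed mood disorders and disturbances,Psychiatric disorders
libido decreased,Sexual desire disorders,Sexual dysfunctions and disturbances,Psychiatric disorders
nausea,Nausea and vomiting symptoms,Gastrointestinal signs and symptoms,Gastrointestinal disorders
vomiting,Nausea and vomiting symptoms,Gastrointestinal signs and symptoms,Gastrointestinal disorders
constipation,Gastrointestinal atonic and hypomotility disorders NEC,Gastrointestinal motility and defaecation conditions,Gastrointestinal disorders
dry mouth,Oral dryness and saliva altered,Gastrointestinal signs and symptoms,Gastrointestinal disorders
abdominal pain,Gastrointestinal and abdominal pains,Gastrointestinal signs and symptoms,Gastrointestinal disorders
fatigue,Asthenic conditions,General system disorders NEC,General disorders and administration site conditions
asthenia,Asthenic conditions,General system disorders NEC,General disorders and administration site conditions
malaise,Feelings and sensations NEC,General system disorders NEC,General disorders and administration site conditions
feeling jittery,Feelings and sensations NEC,General system disorders NEC,General disorders and administration site conditions
pyrexia,General signs and symptoms NEC,General system disorders NEC,General disorders and administration site conditions
chills,General signs and symptoms NEC,General system disorders NEC,General disorders and administration site conditions
pain,Pain and discomfort NEC,General system disorders NEC,General disorders and administration site conditions
chest pain,Pain and discomfort NEC,General system disorders NEC,General disorders and administration site conditions
oedema peripheral,Oedema NEC,General system disorders NEC,General disorders and administration site conditions
death,Death and sudden death,Fatal outcomes,General disorders and administration site conditions
drug ineffective,Therapeutic and nontherapeutic responses,Therapeutic and nontherapeutic effects,General disorders and administration site conditions
drug intolerance,Therapeutic and nontherapeutic responses,Therapeutic and nontherapeutic effects,General disorders and administration site conditions
decreased appetite,Appetite disorders,Appetite and general nutritional disorders,Metabolism and nutrition disorders
diabetes mellitus,Diabetes mellitus (incl subtypes),Glucose metabolism disorders,Metabolism and nutrition disorders
blood pressure increased,Vascular tests NEC (incl blood pressure),Vascular tests,Investigations
heart rate increased,Heart rate and pulse investigations,Cardiac and vascular investigations,Investigations
weight increased,Physical examination procedures and organ system status,Physical examination topics,Investigations
weight decreased,Physical examination procedures and organ system status,Physical examination topics,Investigations
blood creatine phosphokinase increased,Skeletal and cardiac muscle analyses,Enzyme investigations NEC,Investigations
hepatic enzyme increased,Liver function analyses,Hepatobiliary investigations,Investigations
blood cholesterol increased,Cholesterol analyses,Lipid analyses,Investigations
dyspnoea,Breathing abnormalities,Respiratory disorders NEC,Respiratory thoracic and mediastinal disorders
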