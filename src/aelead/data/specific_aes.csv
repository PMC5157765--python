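drug,name,kind,value
atorvastatin,pain,category,Muscle or bone pain
atorvastatin,pain,category,Joint pain
atorvastatin,pain,category,Cramps
atorvastatin,pain,category,Headache
atorvastatin,pain,category,Heart issue or chest pain
atorvastatin,pain,pt,myalgia
atorvastatin,pain,pt,muscle fatigue
atorvastatin,pain,pt,musculoskeletal pain
atorvastatin,pain,pt,musculoskeletal discomfort
atorvastatin,pain,pt,back pain
atorvastatin,pain,pt,pain
atorvastatin,pain,pt,chest pain
sibutramine,cardiovascular,category,Cardiac symptoms
sibutramine,cardiovascular,soc,Cardiac disorders
sibutramine,cardiovascular,soc,Vascular disorders
sibutramine,cardiac,category,Cardiac symptoms
sibutramine,cardiac,soc,Cardiac disorders
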