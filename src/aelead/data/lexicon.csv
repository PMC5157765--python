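drug,category,phrase
atorvastatin,Muscle or bone pain,muscle pain
atorvastatin,Muscle or bone pain,bone pain
atorvastatin,Muscle or bone pain,aching muscles
atorvastatin,Joint pain,joint pain
atorvastatin,Joint pain,joints ache
atorvastatin,Low energy,low energy
atorvastatin,Low energy,no energy
atorvastatin,Mental fog or memory loss,mental fog
atorvastatin,Mental fog or memory loss,memory loss
atorvastatin,Mental fog or memory loss,forgetful
atorvastatin,Cramps,cramp
atorvastatin,Stomach or bowel issues,stomach trouble
atorvastatin,Stomach or bowel issues,bowel
atorvastatin,Stomach or bowel issues,diarrhea
atorvastatin,Weakness,weakness
atorvastatin,Weakness,felt weak
atorvastatin,Depression,depress
atorvastatin,Insomnia,insomnia
atorvastatin,Insomnia,could not sleep
atorvastatin,Numbness,numbness
atorvastatin,Numbness,tingling
atorvastatin,Headache,headache
atorvastatin,Vertigo,vertigo
atorvastatin,Vertigo,dizzy
atorvastatin,Heart issue or chest pain,chest pain
atorvastatin,Heart issue or chest pain,heart pounding
atorvastatin,Heart issue or chest pain,palpitation
atorvastatin,Blurry vision,blurry vision
atorvastatin,Blurry vision,blurred vision
atorvastatin,Swelling,swelling
atorvastatin,Swelling,swollen
atorvastatin,Skin issue,rash
atorvastatin,Skin issue,itchy skin
atorvastatin,Anxiety,anxiety
atorvastatin,Anxiety,anxious
atorvastatin,Urinary issue,urinary
atorvastatin,Urinary issue,urination
atorvastatin,Flu symptoms,flu symptoms
atorvastatin,Flu symptoms,flu-like
atorvastatin,Mood swings,mood swings
sibutramine,Dry mouth,dry mouth
sibutramine,Dry mouth,cotton mouth
sibutramine,Headaches,headache
sibutramine,Insomnia,insomnia
sibutramine,Insomnia,could not sleep
sibutramine,Constipation,constipat
sibutramine,Cardiac symptoms,heart racing
sibutramine,Cardiac symptoms,palpitation
sibutramine,Cardiac symptoms,chest pain
sibutramine,Cardiac symptoms,irregular heartbeat
sibutramine,Anxiety or irritability,anxiety
sibutramine,Anxiety or irritability,anxious
sibutramine,Anxiety or irritability,irritab
sibutramine,Lack of efficacy,did not work
sibutramine,Lack of efficacy,no weight loss
sibutramine,Lack of efficacy,not effective
sibutramine,Nausea or indigestion,nausea
sibutramine,Nausea or indigestion,indigestion
sibutramine,Excessive thirst,thirst
sibutramine,Low energy,low energy
sibutramine,Low energy,no energy
sibutramine,Muscle or joint pain,muscle pain
sibutramine,Muscle or joint pain,joint pain
sibutramine,Hypertension,blood pressure
sibutramine,Hypertension,hypertension
sibutramine,Bad breath,bad breath
sibutramine,Depression,depress
sibutramine,Sexual dysfunction,sex drive
sibutramine,Sexual dysfunction,libido
sibutramine,Sweating,sweat
sibutramine,Skin lesions,skin lesion
sibutramine,Skin lesions,sores on my skin
sibutramine,Shortness of breath,short of breath
sibutramine,Shortness of breath,shortness of breath
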