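concept_id	canonical_name	tuis	synonyms
C0020538	Hypertensive disease	T047	Hypertension|high blood pressure
C9000001	Sepsis	T047	septicemia|blood poisoning
C9000002	Septic shock	T047
C9000003	Pneumonia	T047	lung infection
C9000004	Heart failure	T047	HF|cardiac failure
C9000005	Hypoproteinemia	T047	low serum protein
C9000006	Acute kidney injury	T047	AKI|acute renal failure
C9000007	Fungal infection	T047	mycosis
C9000008	Urinary tract infection	T047	UTI
C9000009	Meningitis	T047
C9000010	Pancreatitis	T047
C9000011	Fever	T184	pyrexia|febrile
C9000012	Tachypnea	T184	rapid breathing
C9000013	Hypotension	T184	low blood pressure
C9000014	Altered mental status	T184
C9000015	Oliguria	T184
C9000016	Dyspnea	T184	shortness of breath
C9000017	Tachycardia	T184	rapid heart rate
C9000018	Abdominal pain	T184
C9000019	Chest X-ray	T060	chest x ray|chest roentgenogram
C9000020	Chest radiograph	T060
C9000021	Abdominal ultrasound	T060	abdominal sonography
C9000022	Chest computed tomography	T060	chest CT
C9000023	Procalcitonin	T116	PCT
C9000024	C-reactive protein	T116	CRP
C9000025	Interleukin 6	T116	IL6
C9000026	Serum lactate	T116	blood lactate
C9000027	Presepsin	T116
C9000028	Blood culture	T059
C9000029	Complete blood count	T059	CBC
C9000030	Arterial blood gas	T059	ABG
C9000031	Urinalysis	T059	urine analysis
C9000032	Urosepsis	T047
C9000033	Neonatal sepsis	T047
C9000034	Surgical sepsis	T047
C9000035	Bacterial infection	T046
C9000036	Gram negative bacteremia	T046
C9000037	Endotoxin release	T046
C9000038	Immune dysregulation	T046
C9000039	Physiological saline	T121	normal saline|saline infusion
C9000040	Glucose infusion	T121	dextrose infusion
C9000041	Vancomycin	T121
C9000042	Meropenem	T121
C9000043	Norepinephrine	T121	noradrenaline
C9000044	Piperacillin tazobactam	T121
C9000045	Abscess drainage	T061
C9000046	Surgical debridement	T061	debridement
C9000047	Appendectomy	T061
C9000048	Source control laparotomy	T061
C9000049	Candida albicans	T004
C9000050	Sinus bradycardia	T047	slow sinus rhythm
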