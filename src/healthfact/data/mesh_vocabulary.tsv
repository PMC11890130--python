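# Mini MeSH descriptor vocabulary covering seven disease areas.
# Synthetic test fixture shaped like the NLM ASCII export reduction:
# descriptor <TAB> tree numbers (';'-separated) <TAB> optional entry terms ('|'-separated)
Arthritis, Rheumatoid	C05.550.114.154;C17.300.775.099	rheumatoid arthritis
Arthritis	C05.550.114
Osteoarthritis	C05.550.114.606.672
Pulmonary Disease, Chronic Obstructive	C08.381.495.389	chronic obstructive pulmonary disease|COPD
Bronchitis, Chronic	C08.127.446.567	chronic bronchitis
Pulmonary Emphysema	C08.381.677	emphysema
COVID-19	C01.748.610.763.500	coronavirus disease 2019|SARS-CoV-2 infection
SARS-CoV-2	B04.820.578.500.540.150.113	severe acute respiratory syndrome coronavirus 2
Hypertension	C14.907.489	high blood pressure
Blood Pressure	G09.330.380.076
Lung Neoplasms	C04.588.894.797.520;C08.381.540;C08.785.520	lung cancer|lung carcinoma
Small Cell Lung Carcinoma	C04.588.894.797.520.055
Prostatic Neoplasms	C04.588.945.440.770;C12.294.260.750	prostate cancer
Prostate	A05.360.444.575
Diabetes Mellitus	C18.452.394.750;C19.246	diabetes
Diabetes Mellitus, Type 2	C18.452.394.750.149;C19.246.300	type 2 diabetes
Insulin	D06.472.699.587.200
Insulin Resistance	C18.452.394.968.500;G07.690.773.984.438
Blood Glucose	D09.400.410.210	blood sugar
Metformin	D02.078.370.141.450
Antihypertensive Agents	D27.505.954.411.097
Antirheumatic Agents	D27.505.954.329.030
Analgesics	D27.505.954.427.040	painkillers
Glucocorticoids	D06.472.040.585.478.383	corticosteroids
Methotrexate	D03.633.100.759.646.138.607
Bronchodilator Agents	D27.505.954.796.380	bronchodilators
Vaccination	E02.095.465.425.400.530.850;N02.421.726.758.310.890	immunization
Drug Therapy	E02.319	drug treatment|medication
Surgical Procedures, Operative	E04	surgery|surgical intervention
Mass Screening	E01.370.500.500;N06.850.780.500.580	screening
Early Detection of Cancer	E01.370.500.250	cancer screening
Physical Examination	E01.370.600	medical examination
Diagnosis	E01
Biopsy	E01.370.225.500.223
Spirometry	E01.370.386.700.750
Radiotherapy	E02.815	radiation therapy
Chemotherapy, Adjuvant	E02.183.750.500	chemotherapy
Risk Factors	N05.715.350.225.625;E05.318.740.600.800.725
Prevalence	N05.715.350.350.700;E05.318.308.985.525.750
Incidence	N05.715.350.350.380;E05.318.308.985.525.375
Mortality	N01.224.935.597;E05.318.308.985.550.400	death rate
Epidemiology	H02.403.720.500.300
Public Health	H02.403.720
Signs and Symptoms	C23.888	symptoms
Pain	C23.888.592.612;F02.830.816.444
Fatigue	C23.888.369.384	tiredness
Cough	C08.618.248;C23.888.852.293
Dyspnea	C08.618.326;C23.888.852.371	shortness of breath
Fever	C23.888.119.344
Muscle Weakness	C05.651.515;C23.888.592.608.500	weakness
Joint Pain	C05.550.091;C23.888.592.612.094	arthralgia
Inflammation	C23.550.470
Smoking	F01.145.466.753.500	tobacco smoking
Obesity	C18.654.726.500;C23.888.144.699.500
Aged	M01.060.116	elderly
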