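phenotype	treatment	consomic	bn_significant	fhh_significant	ss_significant
Plasma lymph abs (E3)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	No	Yes	-
Plasma segmented neutrophils (E3)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	No	Yes	-
Plasma mean corpuscular hemoglobin content (pg)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Plasma mean corpuscular volume (fL)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Plasma red blood cell (E6/uL)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Pre-ischemic heart wet weight (g)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Pre-ischemic heart wet weight (g)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Pre-ischemic left ventricle developed pressure (mmHg)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Pre-ischemic left ventricle systolic pressure (mmHg)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Methacholine ED50 (mg/kg)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Dilator response to acetylcholine EC50 (E-7 mole)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Dilator response to acetylcholine Log EC50 (Log molar)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	No	-
Plasma alk phos (U/L)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Plasma globulin (g/dL)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Plasma hematocrit (%)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Plasma hemoglobin (g/dL)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Plasma phosphorus (mg/dL)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Plasma total protein (g/dL)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Plasma white blood cell count (E3/uL)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Ischemic peak contracture (mmHg)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Body weight (kg)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Body weight (kg)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Body weight (kg)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Lung dry wt (g)/body wt. (kg) ratio (g/kg)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Hematocrit (%)	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Rt ventricle/left ventricle weight ratio (w/w ratio)	12 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
Body weight	21 % O2, 0.4 % salt, male	FHH-YBN/Mcwi	Yes	Yes	-
r @flow = 100 ml/min/g (mmHg x min x kg x ml-1)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	No	-	Yes
Plasma red blood cell (E6/uL)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	No
Dilator response to acetylcholine EC50 (E-7 mole)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	No
Dilator response to acetylcholine Log EC50 (Log molar)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	No
Plasma calcium (mg/dL)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Plasma globulin (g/dL)	21 % O2, 0.4 % Salt, Male	SS-YBN/Mcwi	Yes	-	Yes
Plasma globulin (g/dL)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Plasma hematocrit (%)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Plasma hemoglobin (g/dL)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Plasma hemoglobin (g/dL)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Plasma mono abs (E3)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Plasma potassium (mmol/L)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Plasma red blood cell (E6/uL)	12 % O2, 0.4 % Salt, Male	SS-YBN/Mcwi	Yes	-	Yes
Plasma total protein (g/dL)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Ischemic time to onset of contracture (s)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Ischemic time to peak contracture (s)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Pre-ischemic heart rate (beats/min)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Pre-ischemic heart wet weight (g)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Body weight (kg)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Body weight (kg)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Lung dry wt (g)/body wt. (kg) ratio (g/kg)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Hematocrit (%)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Hematocrit (%)	12 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Body weight (kg)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
Rectal temperature after hypercapnia (C)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
% maximum relaxation acetylcholine (%)	21 % O2, 0.4 % salt, male	SS-YBN/Mcwi	Yes	-	Yes
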