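[
 {
  "name": "Patent ductus arteriosus",
  "icd10": "Q25.0",
  "risk_tier": 0,
  "cyanotic": false,
  "bethesda": "simple"
 },
 {
  "name": "Atrial septal defect",
  "icd10": "Q21.1",
  "risk_tier": 0,
  "cyanotic": false,
  "bethesda": "simple"
 },
 {
  "name": "Atrioventricular septal defect",
  "icd10": "Q21.2",
  "risk_tier": 0,
  "cyanotic": false,
  "bethesda": "moderate"
 },
 {
  "name": "Ventricular septal defect",
  "icd10": "Q21.0",
  "risk_tier": 0,
  "cyanotic": false,
  "bethesda": "simple"
 },
 {
  "name": "Pulmonary artery stenosis",
  "icd10": "Q25.6",
  "risk_tier": 0,
  "cyanotic": false,
  "bethesda": "simple"
 },
 {
  "name": "Aortic coarctation",
  "icd10": "Q25.1",
  "risk_tier": 0,
  "cyanotic": false,
  "bethesda": "moderate"
 },
 {
  "name": "Pulmonary atresia",
  "icd10": "Q25.5",
  "risk_tier": 1,
  "cyanotic": true,
  "bethesda": "complex"
 },
 {
  "name": "Severe pulmonary hypertension",
  "icd10": "I27.0",
  "risk_tier": 1,
  "cyanotic": false,
  "bethesda": "moderate"
 },
 {
  "name": "Anomalous pulmonary venous drainage",
  "icd10": "Q26.2",
  "risk_tier": 1,
  "cyanotic": true,
  "bethesda": "moderate"
 },
 {
  "name": "Tetralogy of Fallot",
  "icd10": "Q21.3",
  "risk_tier": 1,
  "cyanotic": true,
  "bethesda": "complex"
 },
 {
  "name": "Transposition of the great arteries",
  "icd10": "Q20.3",
  "risk_tier": 1,
  "cyanotic": true,
  "bethesda": "complex"
 }
]
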