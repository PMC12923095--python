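voxelotor
icterus
scleral
carcinoma
gallbladder
cancer
mucosa
mucus
mucous
diabetes
hypertension
insulin
asthma
fever
rash
cough
anemia
sepsis
stroke
tumor
lesion
biopsy
dosage
dose
ileum
ilium
humerus
callus
gait
vein
wound
fracture
cardiac
renal
hepatic
pulmonary
neural
seizure
migraine
nausea
vertigo
edema
ulcer
thrombosis
embolism
pneumonia
bronchitis
arthritis
dermatitis
infection
inflammation
discharge
symptom
symptoms
diagnosis
prognosis
therapy
antibiotic
analgesic
pain
flu
palate
clinic
clinical
surgery
surgical
artery
nerve
spine
kidney
liver
lung
heart
blood
cyst
gland
hormone
glucose
oxygen
pulse
scan
xray
mri
triage
vaccine
syringe
scalpel
suture
splint
gauze
ward
nurse
physician
patient
patients
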