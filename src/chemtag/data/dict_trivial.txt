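# TRIVIAL gazetteer (common/trade chemical names), v1
acyclovir
amlodipine
amoxicillin
ampicillin
anethole
artemisinin
aspirin
atenolol
atorvastatin
barbital
berberine
bilirubin
biotin
caffeine
camphor
capsaicin
captopril
carbamazepine
carnitine
celecoxib
cetirizine
chloroquine
cholesterol
choline
cisplatin
citral
colchicine
cortisol
creatine
curcumin
cyclosporine
dexamethasone
diazepam
digoxin
dopamine
doxorubicin
erythromycin
estradiol
ethanol
eugenol
fluoxetine
fructose
furosemide
gabapentin
gefitinib
gemcitabine
gentamicin
geraniol
glucose
glutathione
glycerol
heparin
histamine
ibuprofen
imatinib
inositol
isoniazid
ivermectin
ketamine
lactose
lidocaine
limonene
linalool
loratadine
losartan
maltose
mannitol
melatonin
menthol
metformin
methanol
montelukast
morphine
naproxen
niacin
nicotine
omeprazole
ondansetron
oseltamivir
paclitaxel
paracetamol
penicillin
phenobarbital
prednisone
procaine
progesterone
propranolol
putrescine
quercetin
raffinose
ranitidine
rapamycin
resveratrol
retinol
ribavirin
riboflavin
rifampicin
salbutamol
serotonin
simvastatin
sorbitol
spermidine
streptomycin
sucrose
sumatriptan
tamoxifen
taurine
testosterone
tetracycline
thalidomide
theophylline
thiamine
thymol
tocopherol
topiramate
trehalose
urea
valproate
vancomycin
vanillin
verapamil
warfarin
xylitol
zidovudine
acetic acid
ascorbic acid
citric acid
folic acid
lactic acid
oleic acid
palmitic acid
retinoic acid
salicylic acid
uric acid
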