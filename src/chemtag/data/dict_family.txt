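# FAMILY gazetteer (chemical compound families), v1
alkaloids
aminoglycosides
amphetamines
androgens
anthocyanins
anthraquinones
barbiturates
benzodiazepines
cannabinoids
carotenoids
catechins
catecholamines
cephalosporins
ceramides
chalcones
corticosteroids
coumarins
diterpenes
eicosanoids
estrogens
flavanones
flavonoids
flavonols
gangliosides
glucosinolates
isoflavones
leukotrienes
lignans
lipopolysaccharides
macrolides
naphthoquinones
opioids
oxysterols
penicillins
phenothiazines
phospholipids
polyamines
polyketides
polyphenols
polysaccharides
porphyrins
prostaglandins
purines
pyrimidines
quinolones
retinoids
saponins
sesquiterpenes
sphingolipids
statins
steroids
sterols
stilbenes
sulfonamides
tannins
terpenes
terpenoids
tetracyclines
thromboxanes
tocopherols
triglycerides
triterpenes
xanthines
amino acids
bile acids
essential oils
fatty acids
heavy metals
nucleic bases
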