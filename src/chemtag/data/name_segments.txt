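# chemical name segments (stems, substituents, suffixes), v1
acet
acetyl
al
aldo
allyl
amide
amin
amine
amino
ane
anoate
anoic
anol
anone
anthrac
anthracan
anthracen
anthracoxy
anthracyl
ate
azo
benz
benzan
benzen
benzoxy
benzyl
bicyclo
bis
bromo
but
butan
buten
butoxy
butyl
butyr
capro
carb
carbonyl
carboxy
chloro
cis
cyano
cyclo
dec
decan
decen
decoxy
decyl
dehydro
deoxy
di
dihydro
dodec
dodecan
dodecen
dodecoxy
dodecyl
ene
enoic
epoxy
eth
ethan
ethen
ethoxy
ethyl
fluoro
form
formyl
fructo
furan
furanan
furanen
furanoxy
furanyl
galacto
gluco
glycer
glyco
hept
hepta
heptan
hepten
heptoxy
heptyl
hex
hexa
hexan
hexen
hexoxy
hexyl
hydroperoxy
hydroxy
ide
imidazol
imidazolan
imidazolen
imidazoloxy
imidazolyl
imide
imin
indol
indolan
indolen
indoloxy
indolyl
ine
iodo
iso
isobutyl
isopropyl
isoquinolin
isoquinolinan
isoquinolinen
isoquinolinoxy
isoquinolinyl
keto
manno
meta
meth
methan
methen
methoxy
methyl
mono
naphthal
naphthalan
naphthalen
naphthaloxy
naphthalyl
neo
nitr
nitrile
nitro
non
nonan
nonen
nonoxy
nonyl
oate
oct
octa
octan
octen
octoxy
octyl
ol
oligo
one
ortho
oside
oxazol
oxazolan
oxazolen
oxazoloxy
oxazolyl
oxide
oxo
para
pent
penta
pentan
penten
pentoxy
pentyl
peroxy
phen
phenan
phenen
phenoxy
phenyl
phosph
phospho
poly
porphyrin
prop
propan
propen
propion
propoxy
propyl
pterin
purin
pyridin
pyridinan
pyridinen
pyridinoxy
pyridinyl
pyrimidin
pyrimidinan
pyrimidinen
pyrimidinoxy
pyrimidinyl
pyrrol
pyrrolan
pyrrolen
pyrroloxy
pyrrolyl
quinolin
quinolinan
quinolinen
quinolinoxy
quinolinyl
ribo
sec
spiro
stilben
stilbenan
stilbenen
stilbenoxy
stilbenyl
styr
styran
styren
styroxy
styryl
sulf
sulfo
tert
tetra
tetrahydro
thiazol
thiazolan
thiazolen
thiazoloxy
thiazolyl
thio
thiol
thiophen
thiophenan
thiophenen
thiophenoxy
thiophenyl
tolu
toluan
toluen
toluoxy
toluyl
trans
tri
tris
undec
undecan
undecen
undecoxy
undecyl
valer
vinyl
ylic
yne
ynoic
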