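metabolite,formula,pathway,representative
alanine,C3H7NO2,amino_acid,False
arginine,C6H14N4O2,amino_acid,False
asparagine,C4H8N2O3,amino_acid,False
aspartate,C4H7NO4,amino_acid,False
cysteine,C3H7NO2S,amino_acid,False
glutamate,C5H9NO4,amino_acid,True
glutamine,C5H10N2O3,amino_acid,False
glycine,C2H5NO2,amino_acid,False
histidine,C6H9N3O2,amino_acid,False
isoleucine,C6H13NO2,amino_acid,False
leucine,C6H13NO2,amino_acid,False
lysine,C6H14N2O2,amino_acid,False
methionine,C5H11NO2S,amino_acid,False
phenylalanine,C9H11NO2,amino_acid,False
proline,C5H9NO2,amino_acid,False
serine,C3H7NO3,amino_acid,False
threonine,C4H9NO3,amino_acid,False
tryptophan,C11H12N2O2,amino_acid,False
tyrosine,C9H11NO3,amino_acid,False
valine,C5H11NO2,amino_acid,False
cystine,C6H12N2O4S2,amino_acid_derivative,False
taurine,C2H7NO3S,amino_acid_derivative,False
hypotaurine,C2H7NO2S,amino_acid_derivative,False
sarcosine,C3H7NO2,amino_acid_derivative,False
betaine,C5H11NO2,amino_acid_derivative,False
homocysteine,C4H9NO2S,amino_acid_derivative,False
cystathionine,C7H14N2O4S,amino_acid_derivative,False
N-acetyl-aspartate,C6H9NO5,amino_acid_derivative,True
N-acetyl-glutamate,C7H11NO5,amino_acid_derivative,False
hydroxyproline,C5H9NO3,amino_acid_derivative,False
GABA,C4H9NO2,amino_acid_derivative,False
beta-alanine,C3H7NO2,amino_acid_derivative,False
homoserine,C4H9NO3,amino_acid_derivative,False
O-phosphoserine,C3H8NO6P,amino_acid_derivative,False
S-adenosyl-methionine,C15H22N6O5S,amino_acid_derivative,False
ornithine,C5H12N2O2,urea_cycle,False
citrulline,C6H13N3O3,urea_cycle,True
argininosuccinate,C10H18N4O6,urea_cycle,False
urea,CH4N2O,urea_cycle,False
carbamoyl-phosphate,CH4NO5P,urea_cycle,False
N-acetyl-ornithine,C7H14N2O3,urea_cycle,False
putrescine,C4H12N2,polyamine,False
spermidine,C7H19N3,polyamine,True
spermine,C10H26N4,polyamine,False
N-acetylputrescine,C6H14N2O,polyamine,False
5-methylthioadenosine,C11H15N5O3S,polyamine,False
uracil,C4H4N2O2,pyrimidine,False
uridine,C9H12N2O6,pyrimidine,False
UMP,C9H13N2O9P,pyrimidine,True
UDP,C9H14N2O12P2,pyrimidine,True
UTP,C9H15N2O15P3,pyrimidine,True
cytosine,C4H5N3O,pyrimidine,False
cytidine,C9H13N3O5,pyrimidine,False
CMP,C9H14N3O8P,pyrimidine,False
CDP,C9H15N3O11P2,pyrimidine,False
CTP,C9H16N3O14P3,pyrimidine,False
thymine,C5H6N2O2,pyrimidine,False
thymidine,C10H14N2O5,pyrimidine,False
dTMP,C10H15N2O8P,pyrimidine,False
orotate,C5H4N2O4,pyrimidine,False
dihydroorotate,C5H6N2O4,pyrimidine,False
N-carbamoyl-aspartate,C5H8N2O5,pyrimidine,False
adenine,C5H5N5,purine,False
adenosine,C10H13N5O4,purine,False
AMP,C10H14N5O7P,purine,False
ADP,C10H15N5O10P2,purine,False
ATP,C10H16N5O13P3,purine,False
guanine,C5H5N5O,purine,False
guanosine,C10H13N5O5,purine,False
GMP,C10H14N5O8P,purine,False
GDP,C10H15N5O11P2,purine,False
GTP,C10H16N5O14P3,purine,False
hypoxanthine,C5H4N4O,purine,False
inosine,C10H12N4O5,purine,False
IMP,C10H13N4O8P,purine,True
xanthine,C5H4N4O2,purine,False
urate,C5H4N4O3,purine,False
allantoin,C4H6N4O3,purine,False
glutathione,C10H17N3O6S,redox,True
glutathione-disulfide,C20H32N6O12S2,redox,False
cysteinylglycine,C5H10N2O3S,redox,False
gamma-glutamylcysteine,C8H14N2O5S,redox,False
nicotinamide,C6H6N2O,nad,False
nicotinate,C6H5NO2,nad,False
NAD,C21H27N7O14P2,nad,True
NADP,C21H28N7O17P3,nad,False
NMN,C11H15N2O8P,nad,False
quinolinate,C7H5NO4,nad,False
creatine,C4H9N3O2,creatine,True
creatinine,C4H7N3O,creatine,False
phosphocreatine,C4H10N3O5P,creatine,False
guanidinoacetate,C3H7N3O2,creatine,False
glucosamine,C6H13NO5,amino_sugar,False
glucosamine-6-phosphate,C6H14NO8P,amino_sugar,False
N-acetylglucosamine,C8H15NO6,amino_sugar,False
N-acetylglucosamine-6-phosphate,C8H16NO9P,amino_sugar,False
UDP-GlcNAc,C17H27N3O17P2,amino_sugar,True
choline,C5H13NO,choline,True
phosphocholine,C5H14NO4P,choline,False
glycerophosphocholine,C8H20NO6P,choline,False
CDP-choline,C14H26N4O11P2,choline,False
ammonium,NH3,inorganic,True
nitrate,NO3,inorganic,False
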