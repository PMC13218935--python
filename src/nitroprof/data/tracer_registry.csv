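tracer,nutrient,n_labelled,element,proteinogenic
alanine,alanine,1,N,True
arginine,arginine,4,N,True
asparagine,asparagine,2,N,True
aspartate,aspartate,1,N,True
cysteine,cysteine,1,N,True
glutamate,glutamate,1,N,True
glutamine,glutamine,2,N,True
glycine,glycine,1,N,True
histidine,histidine,3,N,True
isoleucine,isoleucine,1,N,True
leucine,leucine,1,N,True
lysine,lysine,2,N,True
methionine,methionine,1,N,True
phenylalanine,phenylalanine,1,N,True
proline,proline,1,N,True
serine,serine,1,N,True
threonine,threonine,1,N,True
tryptophan,tryptophan,2,N,True
tyrosine,tyrosine,1,N,True
valine,valine,1,N,True
taurine,taurine,1,N,False
ornithine,ornithine,2,N,False
citrulline,citrulline,3,N,False
hypoxanthine,hypoxanthine,4,N,False
uridine,uridine,2,N,False
nitrate,nitrate,1,N,False
ammonium,ammonium,1,N,False
urea,urea,2,N,False
urate,urate,4,N,False
glutamine-amide,glutamine,1,N,False
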