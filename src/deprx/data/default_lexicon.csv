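canonical_name,category,synonyms,components,component_strengths
insulin glargine,INSULIN,lantus|basaglar|toujeo|semglee|glargine,,
insulin lispro,INSULIN,humalog|admelog|lispro,,
insulin aspart,INSULIN,novolog|fiasp|aspart,,
insulin detemir,INSULIN,levemir|detemir,,
insulin degludec,INSULIN,tresiba|degludec,,
insulin glulisine,INSULIN,apidra|glulisine,,
insulin nph,INSULIN,humulin n|novolin n|nph insulin|nph,,
insulin regular,INSULIN,humulin r|novolin r|regular insulin,,
insulin 70-30,INSULIN,humulin 70-30|novolin 70-30|novolog mix 70-30,,
metformin,METFORMIN,glucophage|metformin hcl|metformin hydrochloride,,
metformin er,METFORMIN,glucophage xr|glumetza|fortamet|metformin xr|metformin extended release,,
metformin oral solution,METFORMIN,riomet,,
sitagliptin,NON_INSULIN_OTHER,januvia,,
saxagliptin,NON_INSULIN_OTHER,onglyza,,
linagliptin,NON_INSULIN_OTHER,tradjenta,,
alogliptin,NON_INSULIN_OTHER,nesina,,
glipizide,NON_INSULIN_OTHER,glucotrol|glucotrol xl|glipizide er,,
glyburide,NON_INSULIN_OTHER,diabeta|micronase|glynase,,
glimepiride,NON_INSULIN_OTHER,amaryl,,
pioglitazone,NON_INSULIN_OTHER,actos,,
rosiglitazone,NON_INSULIN_OTHER,avandia,,
empagliflozin,NON_INSULIN_OTHER,jardiance,,
dapagliflozin,NON_INSULIN_OTHER,farxiga,,
canagliflozin,NON_INSULIN_OTHER,invokana,,
ertugliflozin,NON_INSULIN_OTHER,steglatro,,
liraglutide,NON_INSULIN_OTHER,victoza|saxenda,,
semaglutide,NON_INSULIN_OTHER,ozempic|rybelsus|wegovy,,
dulaglutide,NON_INSULIN_OTHER,trulicity,,
exenatide,NON_INSULIN_OTHER,byetta|bydureon,,
tirzepatide,NON_INSULIN_OTHER,mounjaro|zepbound,,
acarbose,NON_INSULIN_OTHER,precose,,
miglitol,NON_INSULIN_OTHER,glyset,,
repaglinide,NON_INSULIN_OTHER,prandin,,
nateglinide,NON_INSULIN_OTHER,starlix,,
sitagliptin-metformin 50-500,NON_INSULIN_OTHER,janumet 50-500,sitagliptin|metformin,50|500
sitagliptin-metformin 50-1000,NON_INSULIN_OTHER,janumet 50-1000,sitagliptin|metformin,50|1000
empagliflozin-metformin 12.5-1000,NON_INSULIN_OTHER,synjardy 12.5-1000,empagliflozin|metformin,12.5|1000
glyburide-metformin 5-500,NON_INSULIN_OTHER,glucovance 5-500,glyburide|metformin,5|500
glipizide-metformin,NON_INSULIN_OTHER,metaglip,glipizide|metformin,
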