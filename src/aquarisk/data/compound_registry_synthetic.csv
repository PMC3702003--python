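# Compound registry: 17 pharmaceuticals detected in the 13-city tap-water survey.
# One row per toxicity basis; derived dose (ADI or RSD, ug/kg/day) = pod / composite_uf.
# Provenance: SYNTHETIC reconstruction. Anchored entries: dimetridazole (MTD 4200
# ug/kg/day, benign mammary tumours in rats, RSD calibrated to the published
# age-dependent DWEL span 27.8-184 ng/L at a 1e-6 lifetime risk), caffeine (RSC 0.1,
# ADI 150 ug/kg/day = registry maximum), thiamphenicol (haemotoxicity),
# sulfamethazine (thyroid follicular adenoma), clarithromycin (gut-flora
# inhibition). Remaining points of departure and uncertainty factors are
# representative screening-level values, not verbatim transcriptions.
# Origin note: salicylic acid and thiamphenicol are marked origin=both (natural/food
# salicylate sources; dual human and veterinary thiamphenicol use), which excludes
# them from indicator selection.
compound,therapeutic_class,origin,chlorination_treatable,route,pod_value_ug_kg_day,pod_kind,endpoint,composite_uf,target_risk_level,rsc
caffeine,psychoactive stimulant,municipal,false,toxicological,15000,NOAEL,cardiovascular and CNS effects,100,,0.1
salicylic acid,NSAID,both,true,therapeutic,24000,lowest_therapeutic_dose,anti-inflammatory lowest daily dose,1000,,1.0
diclofenac,NSAID,municipal,true,therapeutic,500,lowest_therapeutic_dose,anti-inflammatory lowest daily dose,1000,,1.0
clofibric acid,lipid regulator,municipal,false,therapeutic,10000,lowest_therapeutic_dose,lipid-lowering lowest daily dose,1000,,1.0
carbamazepine,anticonvulsant,municipal,false,therapeutic,3400,lowest_therapeutic_dose,anticonvulsant lowest daily dose,10000,,1.0
metoprolol,beta-blocker,municipal,false,therapeutic,1400,lowest_therapeutic_dose,antihypertensive lowest daily dose,100,,1.0
sulfamethoxazole,sulfonamide antibiotic,municipal,true,toxicological,1300,NOAEL,thyroid and body-weight effects,100,,1.0
clarithromycin,macrolide antibiotic,municipal,false,microbiological,1.4,MIC_derived_intake,inhibition of human intestinal microbes,10,,1.0
roxithromycin,macrolide antibiotic,municipal,false,microbiological,5,MIC_derived_intake,inhibition of human intestinal microbes,10,,1.0
azithromycin,macrolide antibiotic,municipal,false,microbiological,5,MIC_derived_intake,inhibition of human intestinal microbes,10,,1.0
trimethoprim,antibiotic,municipal,false,toxicological,420,NOAEL,chronic rodent toxicity,100,,1.0
dimetridazole,nitroimidazole antibiotic,veterinary,false,carcinogenic,4200,MTD,benign mammary tumours in rats,635401,1e-06,1.0
metronidazole,nitroimidazole antibiotic,veterinary,false,therapeutic,7500,lowest_therapeutic_dose,antiprotozoal lowest daily dose,1000,,1.0
thiamphenicol,amphenicol antibiotic,both,false,toxicological,500,NOAEL,haemotoxic effects,1000,,1.0
sulfamethazine,sulfonamide antibiotic,veterinary,true,carcinogenic,12000,MTD,thyroid gland follicular adenoma,20000,1e-05,1.0
sulfathiazole,sulfonamide antibiotic,veterinary,true,toxicological,5000,NOAEL,thyroid effects in rodents,100,,1.0
tylosin,macrolide antibiotic,veterinary,false,microbiological,300,MIC_derived_intake,inhibition of human intestinal microbes,10,,1.0
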