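# Reference occurrence summary for the 13-city, n=113 tap-water survey the package
# models: per-compound detection frequency, median and maximum detected
# concentration (ng/L).
# Provenance: SYNTHETIC reconstruction. Frequencies/medians/maxima for caffeine,
# salicylic acid, clofibric acid, carbamazepine, the macrolides, sulfamethoxazole,
# dimetridazole, metronidazole, sulfamethazine (max) and thiamphenicol (max) follow
# published survey results; remaining entries (and the salicylic/clofibric/
# carbamazepine frequency split within the published 23-33% band) are
# representative reconstructions.
compound,detection_frequency,median_ng_L,max_ng_L
caffeine,0.88,24.4,564
metronidazole,0.40,1.8,19.3
salicylic acid,0.33,16.6,41.2
carbamazepine,0.31,1.3,6.7
clofibric acid,0.23,1.2,3.3
dimetridazole,0.20,6.9,14.7
thiamphenicol,0.12,15.0,104.3
clarithromycin,0.088,6.7,11.9
roxithromycin,0.080,2.8,15.1
azithromycin,0.075,7.1,11.7
sulfamethoxazole,0.071,8.0,21.3
sulfamethazine,0.053,17.8,89.6
trimethoprim,0.035,2.0,5.1
diclofenac,0.027,4.5,10.6
tylosin,0.027,3.5,7.0
sulfathiazole,0.009,9.7,9.7
metoprolol,0.009,1.7,1.7
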