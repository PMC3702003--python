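# Life-stage drinking-water exposure factors: 95th-percentile consumers-only
# community-water ingestion per body weight (mL/kg/day), 12 intervals, birth to 70 y.
# Provenance: values in the style of the U.S. EPA Exposure Factors Handbook (2011),
# ch. 3 (consumers-only, community water). This table is a SYNTHETIC reconstruction:
# the infant (238), early-adolescent minimum (36) and adult (41) rates are anchored
# to published screening-assessment results; remaining entries are representative
# handbook-style values, not a verbatim transcription.
label,age_start_years,age_end_years,ingestion_rate_mL_per_kg_day
birth to <1 month,0,0.0833333,238
1 to <3 months,0.0833333,0.25,228
3 to <6 months,0.25,0.5,158
6 to <12 months,0.5,1,113
1 to <2 years,1,2,64
2 to <3 years,2,3,60
3 to <6 years,3,6,51
6 to <11 years,6,11,46
11 to <16 years,11,16,36
16 to <18 years,16,18,37
18 to <21 years,18,21,38
21 to <70 years,21,70,41
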