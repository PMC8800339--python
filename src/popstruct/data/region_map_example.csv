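country,region
AFR_country1a,AFR_region1
AFR_country1b,AFR_region1
AFR_country2a,AFR_region2
AFR_country2b,AFR_region2
EUR_country1a,EUR_region1
EUR_country1b,EUR_region1
EUR_country2a,EUR_region2
EUR_country2b,EUR_region2
SAS_country1a,SAS_region1
SAS_country1b,SAS_region1
SAS_country2a,SAS_region2
SAS_country2b,SAS_region2
EAS_country1a,EAS_region1
EAS_country1b,EAS_region1
EAS_country2a,EAS_region2
EAS_country2b,EAS_region2
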