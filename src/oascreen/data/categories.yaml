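# Default keyword map for the four broad functional categories of the
# screen. Keywords are case-insensitive regex patterns matched against
# the cluster description and KOG class; they are seeded from the gene
# families recurrently named in coccolithophore carbonate-system and
# light-acclimation studies, and are deliberately broad (sensu latu).
carbon_metabolism:
  - glycolys
  - glucose-6-phosphate
  - phosphoglycerat
  - phosphogluco
  - pentose phosphate
  - fructose-[0-9],[0-9]-bisphosphat
  - trehalose
  - glucan
  - glucosidase
  - glycosyl
  - acetylglucosamine
  - carbonic anhydrase
  - malate
  - pyruvate
  - lactate dehydrogenase
  - enolase
  - oxoacyl
  - acyl-coa
  - lipid
  - fatty acid
  - isocitrate lyase
  - glyceraldehyde-3-phosphate
  - ribulose
light_reactions:
  - chlorophyll
  - fucoxanthin
  - carotenoid
  - phytoene
  - xanthin
  - xanthophyll
  - photosystem
  - light.harvest
  - porphobilinogen
  - uroporphyrinogen
  - protoporphyrin
signaling:
  - kinase
  - phosphatidylinositol
  - sphingosine
  - cbl-interacting
  - calmodulin
  - inositol
  - second messenger
ion_fluxes:
  - antiporter
  - exchanger
  - ion channel
  - " channel"
  - atpase
  - transporter
  - ef-hand
  - bicarbonate
  - translocat
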