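# Three-level habitat classification used to label 16S sampling experiments.
# 5 supertypes, 20 types, 46 subtypes.  Types without an explicit finer
# division act as their own subtype (empty list below), which is how the
# subtype level reaches 46 categories.  The special "Unknown" category for
# unclassifiable samples is handled separately and is not part of the scheme.
Aquatic:
  Saline waters:
    - Coastal waters
    - Open waters
    - Deep waters
    - Lakes
    - Other
  Saline sediment: []
  Freshwaters:
    - Aquifers
    - Groundwaters
    - Lakes
    - Rivers
    - Drinking waters
    - Wastewaters
  Freshwater sediment: []
  Freshwaters-Saline waters interfase: []
  Marine host-associated: []
Terrestrial:
  Soil:
    - Agricultural
    - Arctic
    - Arid
    - Cave
    - Forest
    - Grassland
    - Rocks
    - Saline
    - Other
  Plants:
    - Rhizosphere
    - Other
Thermal:
  Hydrothermal: []
  Geothermal: []
Host-associated:
  Animal host: []
  Gastrointestinal tract:
    - Human
    - Cattle
    - Mouse
    - Insect
    - Other
  Oral: []
  Vagina: []
  Other tissue: []
Other:
  Aerial: []
  Oil: []
  Artificial:
    - Compost
    - Food treatment
    - Industrial
    - Mines
    - Other
  Soil-Saline waters interfase: []
  Soil-Freshwaters interfase: []
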