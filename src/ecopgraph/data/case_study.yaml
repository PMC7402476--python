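schema_version: '1'
services:
- {name: Sun, role: raw}
- {name: Soil_nutrients, role: intermediate}
- {name: Pollination, role: intermediate}
- {name: Habitat, role: intermediate}
- {name: Detritus, role: intermediate}
- {name: Food_for_Herbivore1, role: intermediate}
- {name: Food_for_Herbivore2, role: intermediate}
- {name: Food_for_Carnivore, role: intermediate}
- {name: Food_for_humans, role: product}
units:
- name: Plant1
  inputs: [Pollination, Soil_nutrients, Sun]
  outputs: [Detritus, Food_for_Herbivore1, Habitat]
- name: Plant2
  inputs: [Pollination, Soil_nutrients, Sun]
  outputs: [Detritus, Food_for_Herbivore1, Food_for_Herbivore2, Food_for_humans, Habitat]
- name: Plant3
  inputs: [Pollination, Soil_nutrients, Sun]
  outputs: [Detritus, Food_for_Herbivore2, Food_for_humans]
- name: Herbivore1
  inputs: [Food_for_Herbivore1, Habitat]
  outputs: [Detritus, Food_for_Carnivore, Pollination]
- name: Herbivore2
  inputs: [Food_for_Herbivore2, Habitat]
  outputs: [Detritus, Food_for_Carnivore, Food_for_humans]
- name: Carnivore
  inputs: [Food_for_Carnivore, Habitat]
  outputs: [Detritus]
- name: Soil_microbes
  inputs: [Detritus]
  outputs: [Soil_nutrients]
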