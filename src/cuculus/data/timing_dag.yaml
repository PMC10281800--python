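endogenous:
- depart_breeding
- complete_sahara_south
- arrive_winter
- depart_winter
- depart_west_africa
- arrive_breeding
exogenous:
  habitat:
    kind: binary
    level: bird
    p: 0.5
  route:
    kind: binary
    level: bird
    p: 0.5
  breeding_lat:
    kind: continuous
    level: bird
    p: 0.5
  breeding_lon:
    kind: continuous
    level: bird
    p: 0.5
  eu_stopover_lat:
    kind: continuous
    level: year
    p: 0.5
  wa_stopover_lon:
    kind: continuous
    level: year
    p: 0.5
edges:
- from: habitat
  to: depart_breeding
  coefficient: 0.05
- from: route
  to: depart_breeding
  coefficient: 0.05
- from: habitat
  to: complete_sahara_south
  coefficient: -0.12
- from: route
  to: complete_sahara_south
  coefficient: 0.08
- from: habitat
  to: arrive_winter
  coefficient: 0.05
- from: route
  to: arrive_winter
  coefficient: 0.05
- from: habitat
  to: depart_winter
  coefficient: -0.15
- from: route
  to: depart_winter
  coefficient: 0.15
- from: habitat
  to: depart_west_africa
  coefficient: 0.05
- from: route
  to: depart_west_africa
  coefficient: 0.05
- from: habitat
  to: arrive_breeding
  coefficient: 0.03
- from: route
  to: arrive_breeding
  coefficient: 0.03
- from: breeding_lon
  to: depart_breeding
  coefficient: 0.653
- from: breeding_lat
  to: depart_breeding
  coefficient: 0.1
- from: breeding_lon
  to: arrive_breeding
  coefficient: 0.05
- from: breeding_lat
  to: arrive_breeding
  coefficient: 0.05
- from: eu_stopover_lat
  to: complete_sahara_south
  coefficient: -0.224
- from: wa_stopover_lon
  to: depart_west_africa
  coefficient: 0.274
- from: depart_breeding
  to: complete_sahara_south
  coefficient: 0.397
- from: complete_sahara_south
  to: arrive_winter
  coefficient: 0.3
- from: arrive_winter
  to: depart_winter
  coefficient: 0.25
- from: depart_winter
  to: depart_west_africa
  coefficient: 0.15
- from: depart_west_africa
  to: arrive_breeding
  coefficient: 0.883
- from: depart_breeding
  to: arrive_breeding
  coefficient: -0.05
- from: complete_sahara_south
  to: arrive_breeding
  coefficient: 0.05
- from: arrive_winter
  to: arrive_breeding
  coefficient: 0.05
- from: depart_winter
  to: arrive_breeding
  coefficient: -0.329
- from: complete_sahara_south
  to: depart_west_africa
  coefficient: 0.516
between_fraction:
  depart_breeding: 0.45
  complete_sahara_south: 0.45
  arrive_winter: 0.45
  depart_winter: 0.45
  depart_west_africa: 0.45
  arrive_breeding: 0.45
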