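{
  "type": "FeatureCollection",
  "features": [
    {
      "type": "Feature",
      "properties": {"name": "breeding_area"},
      "geometry": {"type": "Polygon", "coordinates": [[
        [-8.5, 49.8], [2.0, 49.8], [2.0, 55.0], [-0.5, 59.0],
        [-8.5, 58.5], [-8.5, 49.8]
      ]]}
    },
    {
      "type": "Feature",
      "properties": {"name": "iberia"},
      "geometry": {"type": "Polygon", "coordinates": [[
        [-9.8, 36.0], [-6.0, 36.0], [-1.5, 36.8], [3.3, 41.8], [3.0, 43.5],
        [-2.0, 43.8], [-9.3, 43.8], [-9.8, 36.0]
      ]]}
    },
    {
      "type": "Feature",
      "properties": {"name": "italy"},
      "geometry": {"type": "Polygon", "coordinates": [[
        [6.9, 44.2], [13.6, 46.7], [18.8, 40.4], [15.4, 36.4],
        [11.8, 38.2], [10.2, 42.5], [6.9, 44.2]
      ]]}
    },
    {
      "type": "Feature",
      "properties": {"name": "sahara"},
      "geometry": {"type": "Polygon", "coordinates": [[
        [-17.0, 16.0], [35.0, 16.0], [35.0, 30.0], [12.0, 31.5],
        [-5.0, 31.0], [-17.0, 27.0], [-17.0, 16.0]
      ]]}
    },
    {
      "type": "Feature",
      "properties": {"name": "west_africa"},
      "geometry": {"type": "Polygon", "coordinates": [[
        [-17.0, 4.0], [10.0, 4.0], [10.0, 16.0], [-17.0, 16.0], [-17.0, 4.0]
      ]]}
    },
    {
      "type": "Feature",
      "properties": {"name": "wintering_grounds"},
      "geometry": {"type": "Polygon", "coordinates": [[
        [8.0, -8.0], [32.0, -8.0], [32.0, 4.0], [8.0, 4.0], [8.0, -8.0]
      ]]}
    }
  ]
}
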