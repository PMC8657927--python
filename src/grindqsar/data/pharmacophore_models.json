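{
  "tolerance": 1.5,
  "default_radius": {"hydrophobic": 0.75, "hba": 1.0, "hbd": 0.75},
  "models": [
    {
      "name": "model_1",
      "features": [
        {"id": "Hyd", "kind": "hydrophobic", "radius": 0.75},
        {"id": "HBA1", "kind": "hba", "radius": 1.0},
        {"id": "HBA2", "kind": "hba", "radius": 0.5},
        {"id": "HBD1", "kind": "hbd", "radius": 0.75},
        {"id": "HBD2", "kind": "hbd", "radius": 0.75}
      ],
      "distances": [
        [0, 2.62, 4.79, 5.56, 7.68],
        [2.62, 0, 2.61, 3.64, 5.58],
        [4.79, 2.61, 0, 4.57, 3.11],
        [5.56, 3.64, 4.57, 0, 6.97],
        [7.68, 5.58, 3.11, 6.97, 0]
      ]
    },
    {
      "name": "model_2",
      "features": [
        {"id": "Hyd", "kind": "hydrophobic"},
        {"id": "HBA1", "kind": "hba"},
        {"id": "HBD1", "kind": "hbd"},
        {"id": "HBD2", "kind": "hbd"},
        {"id": "HBD3", "kind": "hbd"}
      ],
      "distances": [
        [0, 2.48, 3.46, 5.56, 7.43],
        [2.48, 0, 4.17, 3.63, 5.58],
        [3.46, 4.17, 0, 6.33, 7.8],
        [5.56, 3.63, 6.33, 0, 7.01],
        [7.43, 5.58, 7.8, 7.01, 0]
      ]
    },
    {
      "name": "model_3",
      "features": [
        {"id": "Hyd", "kind": "hydrophobic"},
        {"id": "HBA", "kind": "hba"},
        {"id": "HBD1", "kind": "hbd"},
        {"id": "HBD2", "kind": "hbd"},
        {"id": "HBD3", "kind": "hbd"}
      ],
      "distances": [
        [0, 3.95, 3.97, 7.09, 7.29],
        [3.95, 0, 3.87, 4.13, 3.41],
        [3.97, 3.87, 0, 2.86, 7.01],
        [7.09, 4.13, 2.86, 0, 2.62],
        [7.29, 3.41, 7.01, 2.62, 0]
      ]
    },
    {
      "name": "model_4",
      "features": [
        {"id": "Hyd1", "kind": "hydrophobic"},
        {"id": "HBA", "kind": "hba"},
        {"id": "HBD1", "kind": "hbd"},
        {"id": "HBD2", "kind": "hbd"},
        {"id": "Hyd2", "kind": "hydrophobic"}
      ],
      "distances": [
        [0, 2.32, 3.19, 7.69, 6.22],
        [2.32, 0, 1.62, 6.91, 4.41],
        [3.19, 1.62, 0, 4.57, 3.17],
        [7.69, 6.91, 4.57, 0, 2.04],
        [6.22, 4.41, 3.17, 2.04, 0]
      ]
    },
    {
      "name": "model_5",
      "features": [
        {"id": "Hyd", "kind": "hydrophobic"},
        {"id": "HBA", "kind": "hba"},
        {"id": "HBD1", "kind": "hbd"},
        {"id": "HBD2", "kind": "hbd"},
        {"id": "HBD3", "kind": "hbd"}
      ],
      "distances": [
        [0, 2.32, 4.56, 2.92, 7.06],
        [2.32, 0, 3.01, 1.05, 5.09],
        [4.56, 3.01, 0, 3.61, 7.53],
        [2.92, 1.05, 3.61, 0, 5.28],
        [7.06, 5.09, 7.53, 5.28, 0]
      ]
    },
    {
      "name": "model_6",
      "features": [
        {"id": "Hyd", "kind": "hydrophobic"},
        {"id": "HBA1", "kind": "hba"},
        {"id": "HBA2", "kind": "hba"},
        {"id": "HBD1", "kind": "hbd"},
        {"id": "HBD2", "kind": "hbd"}
      ],
      "distances": [
        [0, 4.32, 4.46, 6.87, 4.42],
        [4.32, 0, 2.21, 3.07, 6.05],
        [4.46, 2.21, 0, 5.73, 5.04],
        [6.87, 3.07, 5.73, 0, 9.61],
        [4.42, 6.05, 5.04, 9.61, 0]
      ]
    },
    {
      "name": "model_7",
      "features": [
        {"id": "Hyd", "kind": "hydrophobic"},
        {"id": "HBA", "kind": "hba"},
        {"id": "HBD1", "kind": "hbd"},
        {"id": "HBD2", "kind": "hbd"},
        {"id": "HBD3", "kind": "hbd"}
      ],
      "distances": [
        [0, 2.49, 4.06, 5.08, 6.1],
        [2.49, 0, 2.07, 2.8, 6.48],
        [4.06, 2.07, 0, 2.38, 8.87],
        [5.08, 2.8, 2.38, 0, 6.56],
        [6.1, 6.48, 8.87, 6.56, 0]
      ]
    },
    {
      "name": "model_8",
      "features": [
        {"id": "Hyd", "kind": "hydrophobic"},
        {"id": "HBA1", "kind": "hba"},
        {"id": "HBA2", "kind": "hba"},
        {"id": "HBD", "kind": "hbd"}
      ],
      "distances": [
        [0, 4.28, 4.26, 7.08],
        [4.28, 0, 2.8, 6.94],
        [4.26, 2.8, 0, 5.42],
        [7.08, 6.94, 5.42, 0]
      ]
    },
    {
      "name": "model_9",
      "features": [
        {"id": "HBA1", "kind": "hba"},
        {"id": "HBA2", "kind": "hba"},
        {"id": "HBA3", "kind": "hba"},
        {"id": "HBD1", "kind": "hbd"},
        {"id": "HBD2", "kind": "hbd"}
      ],
      "distances": [
        [0, 2.52, 2.05, 4.65, 6.9],
        [2.52, 0, 2.07, 2.28, 7.96],
        [2.05, 2.07, 0, 4.06, 5.75],
        [4.65, 2.28, 4.06, 0, 8.96],
        [6.9, 7.96, 5.75, 8.96, 0]
      ]
    },
    {
      "name": "model_10",
      "features": [
        {"id": "HBA1", "kind": "hba"},
        {"id": "HBA2", "kind": "hba"},
        {"id": "HBD1", "kind": "hbd"},
        {"id": "HBD2", "kind": "hbd"}
      ],
      "distances": [
        [0, 3.26, 3.65, 6.96],
        [3.26, 0, 6.06, 6.09],
        [3.65, 6.06, 0, 6.33],
        [6.96, 6.09, 6.33, 0]
      ]
    }
  ]
}
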