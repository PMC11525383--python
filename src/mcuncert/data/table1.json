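[
 {"symbol": "S_MH", "description": "Mass of standard working solution in standard blend 2", "value": 97.69, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [97.69, 0.01]}},
 {"symbol": "S_ML", "description": "Mass of standard working solution in standard blend 1", "value": 80.43, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [80.43, 0.01]}},
 {"symbol": "Q_S1", "description": "Mass of reference material in stock solution", "value": 3.63, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [3.63, 0.01]}},
 {"symbol": "Q_ST1", "description": "Total mass of stock solution", "value": 7918.34, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [7918.34, 0.005]}},
 {"symbol": "Q_S2", "description": "Mass of stock solution for dilute solution 1", "value": 804.21, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [804.21, 0.01]}},
 {"symbol": "Q_ST2", "description": "Total mass of dilute solution 1", "value": 9084.56, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [9084.56, 0.005]}},
 {"symbol": "Q_S3", "description": "Mass of dilute solution 1 for dilute solution 2", "value": 531.44, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [531.44, 0.01]}},
 {"symbol": "Q_ST3", "description": "Total mass of dilute solution 2", "value": 46096.5, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [46096.5, 0.005]}},
 {"symbol": "Q_S4", "description": "Mass of dilute solution 2 for working solution", "value": 928.28, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [928.28, 0.01]}},
 {"symbol": "Q_ST4", "description": "Total mass of working solution", "value": 92286.98, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [92286.98, 0.005]}},
 {"symbol": "I_MH", "description": "Mass of internal standard solution in standard blend 2", "value": 88.52, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [88.52, 0.01]}},
 {"symbol": "I_ML", "description": "Mass of internal standard solution in standard blend 1", "value": 88.98, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [88.98, 0.01]}},
 {"symbol": "I_MS", "description": "Mass of internal standard solution in sample blend", "value": 88.2, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [88.2, 0.01]}},
 {"symbol": "W_S", "description": "Mass of sample", "value": 84.53, "unit": "mg", "distribution": {"type": "gaussian", "parameters": [84.53, 0.01]}},
 {"symbol": "R_H", "description": "Peak isotope ratio of standard blend 2", "value": 1.1419, "unit": "", "distribution": {"type": "gaussian", "parameters": [1.1419, 0.01759]}},
 {"symbol": "R_L", "description": "Peak isotope ratio of standard blend 1", "value": 0.94467, "unit": "", "distribution": {"type": "gaussian", "parameters": [0.94467, 0.00911]}},
 {"symbol": "R_S", "description": "Peak isotope ratio of sample blend", "value": 1.00815, "unit": "", "distribution": {"type": "gaussian", "parameters": [1.00815, 0.01185]}},
 {"symbol": "D_S", "description": "Density of sample", "value": 1.024, "unit": "g/mL", "distribution": {"type": "rectangular", "parameters": [1.022, 1.026]}},
 {"symbol": "P", "description": "Purity of reference material", "value": 94.9, "unit": "%", "distribution": {"type": "gaussian", "parameters": [94.9, 0.95]}},
 {"symbol": "M_W", "description": "Relative molecular weight of testosterone", "value": 288.4, "unit": "g/mol", "distribution": null}
]
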