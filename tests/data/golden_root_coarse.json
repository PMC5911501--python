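{
 "description": "coarse idealized aortic root (mesh_size 12 mm), golden I/O fixture",
 "num_vertices": 185,
 "num_cells": 720,
 "dim": 3,
 "region_cell_counts": {
  "1": 576,
  "2": 48,
  "3": 48,
  "4": 48
 },
 "facet_counts": {
  "closure": 36,
  "inlet": 60,
  "interface": 72,
  "outlet": 60,
  "wall": 96
 }
}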