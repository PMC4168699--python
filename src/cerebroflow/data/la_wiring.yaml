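# Leptomeningeal anastomosis wiring.
#
# Inter-territorial connections attach at the fifth-order tips of the six
# MCA cortical arteries that possess them, pairing frontal/parietal
# branches to the ACA and temporal/parietal branches to the PCA.  The
# ACA/PCA partner branch for each pairing is a documented modelling choice.
# Intra-territorial connections chain the fifth-order tips of adjacent
# cortical branches within one territory, in their anatomical order around
# the convexity.  The "{S}-" placeholder expands to both sides (R, L).
inter:
  - ["{S}-orbito-frontal", "{S}-ACA-frontal-1"]
  - ["{S}-precentral", "{S}-ACA-frontal-2"]
  - ["{S}-central", "{S}-ACA-paracentral"]
  - ["{S}-ant-parietal", "{S}-ACA-precuneal"]
  - ["{S}-angular", "{S}-PCA-parieto-occipital"]
  - ["{S}-ant-temporal", "{S}-PCA-temporal"]
intra:
  MCA-{S}:
    - "{S}-orbito-frontal"
    - "{S}-prefrontal"
    - "{S}-precentral"
    - "{S}-central"
    - "{S}-ant-parietal"
    - "{S}-post-parietal"
    - "{S}-angular"
    - "{S}-temporo-occipital"
    - "{S}-post-temporal"
    - "{S}-mid-temporal"
    - "{S}-ant-temporal"
    - "{S}-temporopolar"
  ACA-{S}:
    - "{S}-ACA-frontal-1"
    - "{S}-ACA-frontal-2"
    - "{S}-ACA-paracentral"
    - "{S}-ACA-precuneal"
  PCA-{S}:
    - "{S}-PCA-temporal"
    - "{S}-PCA-parieto-occipital"
    - "{S}-PCA-calcarine"
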