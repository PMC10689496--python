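# Associations between past human societies and biomes across the study area
# (Near East, Caucasus, Balkans, Pontic-Caspian steppe, part of Central Asia),
# per time window in years BP.  Cultures: HG hunter-gatherers, N Neolithic,
# CA Copper Age, BA Bronze Age, IA Iron Age.  AP = arboreal pollen.
windows:
  - span: [15000, 11000]
    HG: [Steppe, AP_5_25, AP_25_50, AP_50_75, AP_GT75]
    N: []
    CA: []
    BA: []
    IA: []
  - span: [11000, 8000]
    HG: [AP_5_25, AP_25_50, AP_50_75, AP_GT75]
    N: [Steppe, AP_5_25, AP_25_50]
    CA: []
    BA: []
    IA: []
  - span: [8000, 6000]
    HG: [AP_GT75]
    N: [Steppe, AP_5_25, AP_25_50]
    CA: [Steppe, AP_5_25, AP_25_50, AP_50_75]
    BA: []
    IA: []
  - span: [6000, 4000]
    HG: [AP_GT75]
    N: []
    CA: [Steppe, AP_5_25, AP_25_50]
    BA: [Steppe, AP_5_25, AP_25_50, AP_50_75]
    IA: []
  - span: [4000, 2000]
    HG: []
    N: []
    CA: []
    BA: [Steppe, AP_5_25, AP_25_50, AP_50_75, AP_GT75]
    IA: [Steppe, AP_5_25, AP_25_50, AP_50_75, AP_GT75]
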