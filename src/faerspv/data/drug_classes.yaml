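# Default drug-class dictionaries for the acid-suppressant / checkpoint-inhibitor
# study groups.  Ingredient names are lower-case; synonyms map brand names or
# common aliases onto ingredients.  Misoprostol sits in the H2RA search class to
# reproduce the keyword grouping used for report retrieval, although it is a
# prostaglandin analogue pharmacologically.
ICI:
  members:
    - pembrolizumab
    - nivolumab
    - cemiplimab
    - durvalumab
    - avelumab
    - atezolizumab
    - tremelimumab
    - ipilimumab
  synonyms:
    keytruda: pembrolizumab
    opdivo: nivolumab
    libtayo: cemiplimab
    imfinzi: durvalumab
    bavencio: avelumab
    tecentriq: atezolizumab
    imjudo: tremelimumab
    yervoy: ipilimumab
PPI:
  members:
    - omeprazole
    - lansoprazole
    - pantoprazole
    - rabeprazole
    - esomeprazole
    - dexlansoprazole
  synonyms:
    prilosec: omeprazole
    losec: omeprazole
    prevacid: lansoprazole
    protonix: pantoprazole
    aciphex: rabeprazole
    pariet: rabeprazole
    nexium: esomeprazole
    dexilant: dexlansoprazole
H2RA:
  members:
    - ranitidine
    - cimetidine
    - famotidine
    - nizatidine
    - misoprostol
    - roxatidine
  synonyms:
    zantac: ranitidine
    tagamet: cimetidine
    pepcid: famotidine
    axid: nizatidine
    cytotec: misoprostol
PCAB:
  members:
    - revaprazan
    - vonoprazan
    - tegoprazan
    - fexuprazan
    - keverprazan
  synonyms:
    voquezna: vonoprazan
    takecab: vonoprazan
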