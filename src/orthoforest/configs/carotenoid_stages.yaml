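# Carotenoid-pathway screening stages.
#
# The published screen's exact per-stage term lists live in supplementary
# material that is not redistributable here; these stages reproduce the
# screen's structure and labels with the GO/Pfam identifiers quoted in the
# article text (carotenoid dioxygenase activity, oxidoreductase activities,
# metal binding, amino-oxidase / carotenoid-oxygenase / Pyr_redox_2
# domains). Supply your own stage file to reproduce a specific published
# trajectory.
stages:
  - label: chloroplast-localized
    connective: OR
    rules:
      - field: keywords
        mode: has_any
        terms: [chloroplast, plastid]
  - label: carotenoid-function GO
    connective: OR
    rules:
      - field: go_terms
        mode: has_any
        terms:
          - "GO:0010436"   # carotenoid dioxygenase activity
          - "GO:0016117"   # carotenoid biosynthetic process
          - "GO:0016730"   # oxidoreductase, acting on iron-sulfur proteins
          - "GO:0016744"   # transketolase/transaldolase activity
          - "GO:0102067"   # geranylgeranyl diphosphate reductase activity
          - "GO:0046608"   # carotenoid isomerase activity
          - "GO:0052887"   # beta,beta-carotene 9',10'-cleaving dioxygenase
          - "GO:0004310"   # farnesyl-diphosphate farnesyltransferase
          - "GO:0046872"   # metal ion binding
  - label: carotenoid-domain Pfam
    connective: OR
    rules:
      - field: pfam_terms
        mode: has_any
        terms:
          - "PF01593"      # amino_oxidase
          - "PF03055"      # carotenoid oxygenase (RPE65)
          - "PF07992"      # Pyr_redox_2
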