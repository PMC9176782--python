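# NSCLC case-finding rule set for SNOMED-coded Italian pathology registries.
#
# Components are boolean expressions over SNOMED code patterns ("*" = prefix)
# and diagnosis-field keyword patterns ("*x*" substring, "x*" token prefix).
# Algorithm versions combine components; the second modification is the final
# version adopted for the region-wide registry.

components:
  Morpho_1:
    description: NSCLC morphology codes, or any M-8* code with an NSCLC histology keyword
    criterion: inclusion
    expression:
      any:
        - code: {axis: morphology, pattern: "M-81403"}
        - code: {axis: morphology, pattern: "M-80703"}
        - code: {axis: morphology, pattern: "M-82463"}
        - code: {axis: morphology, pattern: "M-85603"}
        - code: {axis: morphology, pattern: "M-83233"}
        - code: {axis: morphology, pattern: "M-85503"}
        - code: {axis: morphology, pattern: "M-84303"}
        - code: {axis: morphology, pattern: "M-82503"}
        - code: {axis: morphology, pattern: "M-80033"}
        - code: {axis: morphology, pattern: "M-80123"}
        - code: {axis: morphology, pattern: "M-80463"}
        - all:
            - code: {axis: morphology, pattern: "M-8*"}
            - any:
                - keyword: "*non microcit*"
                - keyword: "*adenocarcin*"
                - keyword: "*squamocell*"
                - keyword: "*grandi cell*"

  Topog_1:
    description: Chest topography codes or lung/bronchus keywords
    criterion: inclusion
    expression:
      any:
        - code: {axis: topography, pattern: "T-2*"}
        - keyword: "POLM*"
        - keyword: "BRONCH*"

  Morpho_K_neuroend:
    description: Neuroendocrine carcinoma morphology
    criterion: exclusion
    expression:
      code: {axis: morphology, pattern: "M-82463"}

  Topog_Upper_airways:
    description: Upper-airway topography
    criterion: exclusion
    expression:
      any:
        - code: {axis: topography, pattern: "T-21*"}
        - code: {axis: topography, pattern: "T-22*"}
        - code: {axis: topography, pattern: "T-23*"}
        - code: {axis: topography, pattern: "T-24*"}
        - code: {axis: topography, pattern: "T-25*"}

  Topog_Resp_Not_specified:
    description: Respiratory system, not otherwise specified
    criterion: exclusion
    expression:
      code: {axis: topography, pattern: "T-20*"}

algorithms:
  first_version:
    expression:
      all:
        - component: Morpho_1
        - component: Topog_1

  first_modification:
    expression:
      all:
        - all:
            - component: Morpho_1
            - not: {component: Morpho_K_neuroend}
        - all:
            - component: Topog_1
            - not:
                any:
                  - component: Topog_Upper_airways
                  - component: Topog_Resp_Not_specified

  second_modification:
    final: true
    expression:
      all:
        - all:
            - component: Morpho_1
            - not: {component: Morpho_K_neuroend}
        - all:
            - component: Topog_1
            - not: {component: Topog_Upper_airways}
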