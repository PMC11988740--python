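# Baseline diagnostic requirements for a mammographic AI model detecting
# signs of breast cancer: the response capabilities its outputs must cover.
id: diagnostic-baseline
version: 1
title: Baseline diagnostic requirements for mammographic AI outputs
items:
  - id: mass-detection
    text: >-
      Detection, segmentation, and classification (benign/malignant) of
      masses.
    predicate: "capability:mass_detection"
  - id: calcification-detection
    text: >-
      Detection, segmentation, and classification (benign/malignant) of
      calcifications.
    predicate: "capability:calcification_detection"
  - id: lymph-node-detection
    text: Detection and segmentation of enlarged lymph nodes.
    predicate: "capability:lymph_node_detection"
  - id: density-category
    text: ACR category of breast density for each breast.
    predicate: "capability:density_category"
  - id: study-probability
    text: Probability of breast cancer in the entire study.
    predicate: "capability:study_probability"
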