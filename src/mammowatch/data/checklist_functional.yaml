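# Baseline functional requirements for the outputs of a radiological AI
# model: additional image series and DICOM Structured Report properties
# that any clinical model must satisfy regardless of modality.
# Item ids are this package's stable identifiers.
id: functional-baseline
version: 1
title: Baseline functional requirements for radiological AI outputs
items:
  - id: series-modified-image
    text: >-
      The additional series contains a modified image for every processed
      study, regardless of the presence of pathological findings.
    predicate: "flag:has_additional_series"
  - id: masks-monochrome-visible
    text: >-
      Graphical masks highlight each target finding and remain
      distinguishable on monochrome mammography monitors.
    predicate: monochrome_masks
  - id: masks-within-organ
    text: Graphical masks do not extend beyond the target organ.
    predicate: "flag:masks_within_organ"
  - id: masks-labeled
    text: >-
      Each finding's graphical mask is labeled by color-coding or a
      numerical identifier.
    predicate: "flag:masks_labeled"
  - id: all-views-processed
    text: All image series (views) are processed.
    predicate: "flag:masks_on_all_views"
  - id: images-uncropped
    text: Images in the additional series are not cropped.
    predicate: "flag:images_uncropped"
  - id: structured-report-template
    text: >-
      A DICOM SR is generated per study with the expected template
      (modality, region of interest, study identifier, clinical task,
      technical parameters, brief user manual).
    predicate: "flag:has_structured_report"
  - id: name-and-version
    text: >-
      The additional series and DICOM SR contain the name and version of
      the AI model.
    predicate: "flag:has_name_and_version"
  - id: analysis-timestamp
    text: >-
      The additional series and DICOM SR contain the date and time of
      analysis completion.
    predicate: "flag:has_timestamp"
  - id: research-only-label
    text: >-
      The additional series and DICOM SR contain the "For research
      purposes only" notification.
    predicate: "flag:has_research_only_label"
  - id: no-contradicting-data
    text: >-
      No contradicting data between the additional series and the DICOM SR
      (e.g. the report omits an impression of a labeled finding).
    predicate: "flag:no_contradictions"
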