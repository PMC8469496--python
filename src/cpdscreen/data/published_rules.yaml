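schema: cpdscreen-rules/1
composite:
  name: composite-neoplastic
  numerator:
  - SD-V-NE
  - MN-UMALS-LY
  - SD-AL2-MO
  cutoff: 106.44
  orientation: high_is_positive
  positive_label: neoplastic
  negative_label: non-neoplastic
  denominator:
  - MN-C-NE
reactive:
  name: reactive-discriminant
  numerator:
  - MN-AL2-NE
  cutoff: 147.5
  orientation: low_is_positive
  positive_label: neoplastic
  negative_label: reactive
subtypes:
  AML:
  - name: SD-MALS-NE
    numerator:
    - SD-MALS-NE
    cutoff: 15.81
    orientation: high_is_positive
    positive_label: AML
    negative_label: other
  - name: SD-UMALS-NE
    numerator:
    - SD-UMALS-NE
    cutoff: 17.7
    orientation: high_is_positive
    positive_label: AML
    negative_label: other
  APL:
  - name: MN-V-NE
    numerator:
    - MN-V-NE
    cutoff: 159.5
    orientation: high_is_positive
    positive_label: APL
    negative_label: other
  - name: SD-V-MO
    numerator:
    - SD-V-MO
    cutoff: 33.68
    orientation: high_is_positive
    positive_label: APL
    negative_label: other
  ALL:
  - name: MN-MALS-NE
    numerator:
    - MN-MALS-NE
    cutoff: 129.5
    orientation: high_is_positive
    positive_label: ALL
    negative_label: other
  - name: MN-LMALS-NE
    numerator:
    - MN-LMALS-NE
    cutoff: 122.5
    orientation: high_is_positive
    positive_label: ALL
    negative_label: other
  CLL:
  - name: SD-C-MO
    numerator:
    - SD-C-MO
    cutoff: 11.1
    orientation: high_is_positive
    positive_label: CLL
    negative_label: other
singles:
- name: SD-V-NE
  numerator:
  - SD-V-NE
  cutoff: 18.95
  orientation: high_is_positive
  positive_label: neoplastic
  negative_label: non-neoplastic
- name: MN-C-NE
  numerator:
  - MN-C-NE
  cutoff: 148.5
  orientation: low_is_positive
  positive_label: neoplastic
  negative_label: non-neoplastic
- name: MN-UMALS-LY
  numerator:
  - MN-UMALS-LY
  cutoff: 59.5
  orientation: high_is_positive
  positive_label: neoplastic
  negative_label: non-neoplastic
- name: SD-AL2-MO
  numerator:
  - SD-AL2-MO
  cutoff: 16.2
  orientation: high_is_positive
  positive_label: neoplastic
  negative_label: non-neoplastic
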