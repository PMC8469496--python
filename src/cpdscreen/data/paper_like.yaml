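seed: 0
roster:
- MN-V-NE
- MN-V-LY
- MN-V-MO
- MN-V-EO
- MN-C-NE
- MN-C-LY
- MN-C-MO
- MN-C-EO
- MN-MALS-NE
- MN-MALS-LY
- MN-MALS-MO
- MN-MALS-EO
- MN-UMALS-NE
- MN-UMALS-LY
- MN-UMALS-MO
- MN-UMALS-EO
- MN-LMALS-NE
- MN-LMALS-LY
- MN-LMALS-MO
- MN-LMALS-EO
- MN-LALS-NE
- MN-LALS-LY
- MN-LALS-MO
- MN-LALS-EO
- MN-AL2-NE
- MN-AL2-LY
- MN-AL2-MO
- MN-AL2-EO
- SD-V-NE
- SD-V-LY
- SD-V-MO
- SD-V-EO
- SD-C-NE
- SD-C-LY
- SD-C-MO
- SD-C-EO
- SD-MALS-NE
- SD-MALS-LY
- SD-MALS-MO
- SD-MALS-EO
- SD-UMALS-NE
- SD-UMALS-LY
- SD-UMALS-MO
- SD-UMALS-EO
- SD-LMALS-NE
- SD-LMALS-LY
- SD-LMALS-MO
- SD-LMALS-EO
- SD-LALS-NE
- SD-LALS-LY
- SD-LALS-MO
- SD-LALS-EO
- SD-AL2-NE
- SD-AL2-LY
- SD-AL2-MO
- SD-AL2-EO
defaults:
  SD-MALS-NE:
  - lognormal
  - 14.0
  - 3.0
  SD-UMALS-NE:
  - lognormal
  - 15.0
  - 3.0
  MN-V-NE:
  - normal
  - 150.0
  - 8.0
  SD-V-MO:
  - lognormal
  - 30.0
  - 5.0
  MN-MALS-NE:
  - normal
  - 126.0
  - 7.0
  MN-LMALS-NE:
  - normal
  - 119.0
  - 7.0
  SD-C-MO:
  - lognormal
  - 9.5
  - 2.0
groups:
- label: normal
  n: 1056
  overrides:
    SD-V-NE:
    - lognormal
    - 15.0
    - 2.2
    MN-C-NE:
    - normal
    - 155.0
    - 4.5
    MN-UMALS-LY:
    - normal
    - 52.0
    - 5.5
    SD-AL2-MO:
    - lognormal
    - 13.0
    - 2.0
    MN-AL2-NE:
    - normal
    - 143.0
    - 6.0
- label: reactive
  n: 47
  overrides:
    SD-V-NE:
    - lognormal
    - 15.0
    - 2.2
    MN-C-NE:
    - normal
    - 155.0
    - 4.5
    MN-UMALS-LY:
    - normal
    - 52.0
    - 5.5
    SD-AL2-MO:
    - lognormal
    - 13.0
    - 2.0
    MN-AL2-NE:
    - normal
    - 156.0
    - 6.0
- label: AML
  n: 62
  overrides:
    SD-V-NE:
    - lognormal
    - 26.0
    - 5.0
    MN-C-NE:
    - normal
    - 142.0
    - 7.5
    MN-UMALS-LY:
    - normal
    - 67.0
    - 8.5
    SD-AL2-MO:
    - lognormal
    - 21.0
    - 4.5
    MN-AL2-NE:
    - normal
    - 141.0
    - 7.0
    SD-MALS-NE:
    - lognormal
    - 16.8
    - 3.2
    SD-UMALS-NE:
    - lognormal
    - 18.0
    - 3.2
- label: APL
  n: 30
  overrides:
    SD-V-NE:
    - lognormal
    - 26.0
    - 5.0
    MN-C-NE:
    - normal
    - 142.0
    - 7.5
    MN-UMALS-LY:
    - normal
    - 67.0
    - 8.5
    SD-AL2-MO:
    - lognormal
    - 21.0
    - 4.5
    MN-AL2-NE:
    - normal
    - 141.0
    - 7.0
    MN-V-NE:
    - normal
    - 158.0
    - 8.0
    SD-V-MO:
    - lognormal
    - 36.0
    - 6.0
- label: ALL
  n: 54
  overrides:
    SD-V-NE:
    - lognormal
    - 26.0
    - 5.0
    MN-C-NE:
    - normal
    - 142.0
    - 7.5
    MN-UMALS-LY:
    - normal
    - 67.0
    - 8.5
    SD-AL2-MO:
    - lognormal
    - 21.0
    - 4.5
    MN-AL2-NE:
    - normal
    - 141.0
    - 7.0
    MN-MALS-NE:
    - normal
    - 132.0
    - 8.0
    MN-LMALS-NE:
    - normal
    - 126.0
    - 8.0
- label: lymphoma
  n: 47
  overrides:
    SD-V-NE:
    - lognormal
    - 26.0
    - 5.0
    MN-C-NE:
    - normal
    - 142.0
    - 7.5
    MN-UMALS-LY:
    - normal
    - 67.0
    - 8.5
    SD-AL2-MO:
    - lognormal
    - 21.0
    - 4.5
    MN-AL2-NE:
    - normal
    - 141.0
    - 7.0
- label: CLL
  n: 28
  overrides:
    SD-V-NE:
    - lognormal
    - 26.0
    - 5.0
    MN-C-NE:
    - normal
    - 142.0
    - 7.5
    MN-UMALS-LY:
    - normal
    - 67.0
    - 8.5
    SD-AL2-MO:
    - lognormal
    - 21.0
    - 4.5
    MN-AL2-NE:
    - normal
    - 141.0
    - 7.0
    SD-C-MO:
    - lognormal
    - 11.8
    - 2.5
- label: CML
  n: 12
  overrides:
    SD-V-NE:
    - lognormal
    - 26.0
    - 5.0
    MN-C-NE:
    - normal
    - 142.0
    - 7.5
    MN-UMALS-LY:
    - normal
    - 67.0
    - 8.5
    SD-AL2-MO:
    - lognormal
    - 21.0
    - 4.5
    MN-AL2-NE:
    - normal
    - 141.0
    - 7.0
- label: MDS
  n: 12
  overrides:
    SD-V-NE:
    - lognormal
    - 26.0
    - 5.0
    MN-C-NE:
    - normal
    - 142.0
    - 7.5
    MN-UMALS-LY:
    - normal
    - 67.0
    - 8.5
    SD-AL2-MO:
    - lognormal
    - 21.0
    - 4.5
    MN-AL2-NE:
    - normal
    - 141.0
    - 7.0
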