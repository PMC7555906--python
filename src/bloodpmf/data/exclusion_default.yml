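# Default exclusion list: CHCA matrix cluster ions and porcine trypsin
# autolysis products inside the 600-2000 Th acquisition window.
# These are generic plumbing defaults, NOT taken from any publication's own
# exclusion lists, and are fully overridable via --exclude.
name: chca-trypsin-default
tolerance_ppm: 15.0
entries:
  - {mz: 677.1281, label: CHCA-cluster}
  - {mz: 869.1398, label: CHCA-cluster}
  - {mz: 1061.1515, label: CHCA-cluster}
  - {mz: 842.5094, label: trypsin-autolysis}
  - {mz: 1045.5642, label: trypsin-autolysis}
  - {mz: 1469.7305, label: trypsin-autolysis}
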