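# Default metadata extraction mapping: DICOM attributes -> sidecar JSON keys.
# BIDS-compatible key names; EchoTime/RepetitionTime kept in milliseconds
# (DICOM native unit), so unit_conversion is 1.0 for them by default.
rules:
  - target_key: Modality
    source_dialect: dicom
    source_address: "(0008,0060)"
  - target_key: SeriesDescription
    source_dialect: dicom
    source_address: "(0008,103E)"
  - target_key: EchoTime
    source_dialect: dicom
    source_address: "(0018,0081)"
    unit_conversion: 1.0
  - target_key: RepetitionTime
    source_dialect: dicom
    source_address: "(0018,0080)"
    unit_conversion: 1.0
  - target_key: FlipAngle
    source_dialect: dicom
    source_address: "(0018,1314)"
  - target_key: AcquisitionDateTime
    source_dialect: dicom
    source_address: "(0008,002A)"
  - target_key: ProtocolName
    source_dialect: dicom
    source_address: "(0018,1030)"
  - target_key: Manufacturer
    source_dialect: dicom
    source_address: "(0008,0070)"
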