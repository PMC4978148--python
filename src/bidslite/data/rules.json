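{
  "version": "1.0.0",
  "required_fields": {
    "bold": ["TaskName", "RepetitionTime"],
    "physio": ["StartTime", "SamplingFrequency"],
    "stim": ["StartTime", "SamplingFrequency"]
  },
  "recommended_fields": {
    "bold": ["SliceTiming", "PhaseEncodingDirection", "EffectiveEchoSpacing", "EchoTime"]
  },
  "required_companions": {
    "bold": [{"suffix": "events", "extension": ".tsv", "unless_task_prefix": "rest"}],
    "dwi": [{"suffix": null, "extension": ".bval"}, {"suffix": null, "extension": ".bvec"}]
  },
  "required_columns": {
    "events": ["onset", "duration"],
    "participants": ["participant_id"]
  },
  "numeric_columns": {
    "events": ["onset", "duration"]
  },
  "required_root_files": ["dataset_description.json"],
  "dataset_description_required_fields": ["Name", "BIDSVersion"],
  "na_heuristic_tokens": ["NA", "N/A", "na", "nan", "NaN", "missing"],
  "suspicious_units": {
    "RepetitionTime": [0.01, 100.0],
    "EchoTime": [1e-06, 1.0],
    "StartTime": [-1000.0, 1000.0],
    "SamplingFrequency": [1e-09, 1000000.0]
  },
  "missing_scan_threshold": 0.5,
  "consistency_fields": [
    "RepetitionTime", "EchoTime", "EffectiveEchoSpacing",
    "SamplingFrequency", "StartTime", "SliceTiming"
  ],
  "tr_conflict_tolerance_s": 0.001,
  "extra_suffixes": [],
  "extra_datatype_suffixes": {}
}
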