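# Issue code catalogue

| Code | Severity | Description |
| --- | --- | --- |
| E_AXES_MISMATCH | error | Axis names mismatch the dimensionality or repeat |
| E_BAD_GRAMMAR | error | Filename token is not a well-formed key-value entity |
| E_BAD_RRID | error | strain_rrid does not match the RRID:<token> pattern |
| E_DERIVED_FROM_CYCLE | error | derived_from references form a cycle |
| E_DERIVED_FROM_UNKNOWN | error | derived_from references no sample of this participant |
| E_DESC_MISSING_KEY | error | dataset_description.json lacks Name or BIDSVersion |
| E_DIM_MISMATCH | error | Point dimensionality mismatches the matrix |
| E_DUP_PARTICIPANT | error | Duplicate participant_id in participants.tsv |
| E_DUP_SAMPLE | error | Duplicate (participant_id, sample_id) pair in samples.tsv |
| E_ENTITY_ORDER | error | Entities appear out of canonical order |
| E_FIELD_TYPE | error | Metadata field value has the wrong type or shape |
| E_JSON_MALFORMED | error | Sidecar JSON could not be parsed |
| E_MATRIX_HOMOGENEOUS | error | Matrix bottom row is not [0, ..., 0, 1] |
| E_MATRIX_SHAPE | error | ChunkTransformationMatrix is not (d+1)x(d+1) |
| E_MISPLACED_FILE | error | Data file is outside its micr/ directory |
| E_MISSING_DATASET_DESCRIPTION | error | dataset_description.json is absent |
| E_MISSING_REQUIRED_ENTITY | error | Filename lacks the subject or sample entity |
| E_MISSING_REQUIRED_FIELD | error | A required metadata field is absent from the sidecar |
| E_MISSING_SAMPLE_TYPE | error | samples.tsv lacks the mandatory sample_type value |
| E_MIXED_AXES | error | Chunks of one group use different axis orders |
| E_MIXED_DIMENSIONALITY | error | Chunks of one group mix 2D and 3D placements |
| E_NOT_A_DATASET | error | No dataset_description.json and no sub-* directories |
| E_OME_HEADER_UNREADABLE | error | OME-TIFF header could not be read or parsed |
| E_PATH_ENTITY_MISMATCH | error | Filename sub/ses labels disagree with the directory |
| E_PIXELSIZE_MISMATCH | error | Sidecar PixelSize disagrees with the OME header |
| E_ROOT_NOT_EMPTY | error | Target directory for generation is not empty |
| E_SAMPLES_TSV_MISSING | error | samples.tsv absent although sample entities are present |
| E_SAMPLE_NOT_IN_TABLE | error | A (subject, sample) pair on disk is absent from samples.tsv |
| E_SCALE_ZERO | error | A scale term of the transformation is zero |
| E_SIDECAR_ENTITY_SUPERSET | error | Sidecar carries entities its data file lacks |
| E_TSV_MALFORMED | error | TSV is ragged, has an empty header, or duplicate columns |
| E_UNKNOWN_CATEGORY | error | Metadata category is not one of the four registered |
| E_UNKNOWN_DEFECT | error | Defect code not in the mutation catalogue |
| E_UNKNOWN_ENTITY | error | Filename uses an entity key not in the microscopy grammar |
| E_UNKNOWN_EXTENSION | error | Extension is not one of .png/.tif/.ome.tif/.ome.btf |
| E_UNKNOWN_SAMPLE_TYPE | error | sample_type is outside the biosample-type vocabulary |
| E_UNKNOWN_SUFFIX | error | Suffix is not a registered microscopy modality |
| E_UNKNOWN_VOCABULARY | error | No controlled vocabulary registered under this name |
| E_UNSUPPORTED_TRANSFORM | error | Rotation/shear present; stitching is undefined |
| E_VOCAB_VIOLATION | error | Metadata field value outside its controlled vocabulary |
| E_WRITE_FAILED | error | Could not write the requested fixture file |
| W_MISSING_RECOMMENDED_FIELD | warning | A recommended metadata field is absent (strict mode) |
| W_NONAXIAL_TRANSFORM | warning | Matrix has off-diagonal terms beyond scaling+translation |
| W_NON_MICR_DATA | warning | Non-microscopy data type directory skipped |
| W_NO_PARTICIPANTS_TABLE | warning | participants.tsv is recommended but absent |
| W_PAD_INCONSISTENT | warning | Inconsistent index zero-padding within one group |
| W_SAMPLE_UNUSED | warning | samples.tsv row never seen among data filenames |
| W_SPECIES_NOT_BINOMIAL | warning | species is not a two-word lowercase binomial name |
| W_STAIN_UNDESCRIBED | warning | stain entity present but no staining metadata given |
| W_VERSION_PREDATES_MICROSCOPY | warning | BIDSVersion predates the microscopy data type (1.7.0) |
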