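# Sample metadata fields (registry 1.7.0)

| Field | Level | Kind | Vocabulary |
| --- | --- | --- | --- |
| BodyPart | recommended | vocab | BodyPart |
| BodyPartDetails | optional | string |  |
| SampleEmbedding | optional | string |  |
| SampleEnvironment | recommended | vocab | SampleEnvironment |
| SampleExtractionInstitution | recommended | string |  |
| SampleExtractionProtocol | recommended | string |  |
| SampleFixation | recommended | string |  |
| SamplePrimaryAntibody | recommended | string |  |
| SampleSecondaryAntibody | recommended | string |  |
| SampleStaining | recommended | string |  |
| SliceThickness | optional | number |  |
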