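# ChunkTransformations metadata fields (registry 1.7.0)

| Field | Level | Kind | Vocabulary |
| --- | --- | --- | --- |
| ChunkTransformationMatrix | recommended | matrix |  |
| ChunkTransformationMatrixAxis | recommended | string-array |  |
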