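# ImageAcquisition metadata fields (registry 1.7.0)

| Field | Level | Kind | Vocabulary |
| --- | --- | --- | --- |
| ImageAcquisitionProtocol | recommended | string |  |
| Immersion | optional | string |  |
| Magnification | recommended | number |  |
| NumericalAperture | optional | number |  |
| OtherAcquisitionParameters | optional | string |  |
| PixelSize | required | number-array |  |
| PixelSizeUnits | required | vocab | PixelSizeUnits |
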