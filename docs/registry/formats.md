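# File formats (registry 1.7.0)

| Extension | Family | Tiled allowed | Embedded metadata |
| --- | --- | --- | --- |
| .ome.btf | OME-TIFF | true | true |
| .ome.tif | OME-TIFF | true | true |
| .png | PNG | false | false |
| .tif | TIFF | false | false |
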