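# DeviceHardware metadata fields (registry 1.7.0)

| Field | Level | Kind | Vocabulary |
| --- | --- | --- | --- |
| DeviceSerialNumber | optional | string |  |
| InstitutionAddress | optional | string |  |
| InstitutionName | recommended | string |  |
| InstitutionalDepartmentName | optional | string |  |
| Manufacturer | recommended | string |  |
| ManufacturersModelName | recommended | string |  |
| SoftwareVersions | optional | string |  |
| StationName | optional | string |  |
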