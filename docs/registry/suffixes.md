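# Modality suffixes (registry 1.7.0)

| Suffix | Modality |
| --- | --- |
| 2PE | two-photon excitation microscopy |
| BF | bright-field microscopy |
| CARS | coherent anti-Stokes Raman spectroscopy |
| CONF | confocal microscopy |
| DF | dark-field microscopy |
| DIC | differential interference contrast microscopy |
| FLUO | fluorescence microscopy |
| MPE | multi-photon excitation microscopy |
| NLO | non-linear optical microscopy |
| OCT | optical coherence tomography |
| PC | phase-contrast microscopy |
| PLI | polarized-light microscopy |
| SEM | scanning electron microscopy |
| SPIM | selective plane illumination microscopy |
| SR | super-resolution microscopy |
| TEM | transmission electron microscopy |
| uCT | Micro-CT |
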