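{
  "registry_version": "1.7.0",
  "suffixes": {
    "TEM": "transmission electron microscopy",
    "SEM": "scanning electron microscopy",
    "uCT": "Micro-CT",
    "BF": "bright-field microscopy",
    "DF": "dark-field microscopy",
    "PC": "phase-contrast microscopy",
    "DIC": "differential interference contrast microscopy",
    "FLUO": "fluorescence microscopy",
    "CONF": "confocal microscopy",
    "PLI": "polarized-light microscopy",
    "CARS": "coherent anti-Stokes Raman spectroscopy",
    "2PE": "two-photon excitation microscopy",
    "MPE": "multi-photon excitation microscopy",
    "SR": "super-resolution microscopy",
    "NLO": "non-linear optical microscopy",
    "OCT": "optical coherence tomography",
    "SPIM": "selective plane illumination microscopy"
  },
  "formats": [
    {"extension": ".png", "family": "PNG", "tiled_allowed": false, "carries_embedded_metadata": false},
    {"extension": ".tif", "family": "TIFF", "tiled_allowed": false, "carries_embedded_metadata": false},
    {"extension": ".ome.tif", "family": "OME-TIFF", "tiled_allowed": true, "carries_embedded_metadata": true},
    {"extension": ".ome.btf", "family": "OME-TIFF", "tiled_allowed": true, "carries_embedded_metadata": true}
  ],
  "categories": {
    "DeviceHardware": [
      {"name": "Manufacturer", "level": "recommended", "value_kind": "string"},
      {"name": "ManufacturersModelName", "level": "recommended", "value_kind": "string"},
      {"name": "DeviceSerialNumber", "level": "optional", "value_kind": "string"},
      {"name": "StationName", "level": "optional", "value_kind": "string"},
      {"name": "SoftwareVersions", "level": "optional", "value_kind": "string"},
      {"name": "InstitutionName", "level": "recommended", "value_kind": "string"},
      {"name": "InstitutionAddress", "level": "optional", "value_kind": "string"},
      {"name": "InstitutionalDepartmentName", "level": "optional", "value_kind": "string"}
    ],
    "ImageAcquisition": [
      {"name": "PixelSize", "level": "required", "value_kind": "number-array"},
      {"name": "PixelSizeUnits", "level": "required", "value_kind": "vocab", "vocabulary": "PixelSizeUnits"},
      {"name": "Immersion", "level": "optional", "value_kind": "string"},
      {"name": "NumericalAperture", "level": "optional", "value_kind": "number"},
      {"name": "Magnification", "level": "recommended", "value_kind": "number"},
      {"name": "ImageAcquisitionProtocol", "level": "recommended", "value_kind": "string"},
      {"name": "OtherAcquisitionParameters", "level": "optional", "value_kind": "string"}
    ],
    "Sample": [
      {"name": "BodyPart", "level": "recommended", "value_kind": "vocab", "vocabulary": "BodyPart"},
      {"name": "BodyPartDetails", "level": "optional", "value_kind": "string"},
      {"name": "SampleEnvironment", "level": "recommended", "value_kind": "vocab", "vocabulary": "SampleEnvironment"},
      {"name": "SampleEmbedding", "level": "optional", "value_kind": "string"},
      {"name": "SampleFixation", "level": "recommended", "value_kind": "string"},
      {"name": "SampleStaining", "level": "recommended", "value_kind": "string"},
      {"name": "SamplePrimaryAntibody", "level": "recommended", "value_kind": "string"},
      {"name": "SampleSecondaryAntibody", "level": "recommended", "value_kind": "string"},
      {"name": "SliceThickness", "level": "optional", "value_kind": "number"},
      {"name": "SampleExtractionProtocol", "level": "recommended", "value_kind": "string"},
      {"name": "SampleExtractionInstitution", "level": "recommended", "value_kind": "string"}
    ],
    "ChunkTransformations": [
      {"name": "ChunkTransformationMatrix", "level": "recommended", "value_kind": "matrix"},
      {"name": "ChunkTransformationMatrixAxis", "level": "recommended", "value_kind": "string-array"}
    ]
  },
  "vocabularies": {
    "sample_type": [
      "cell line",
      "in vitro differentiated cells",
      "primary cell",
      "cell-free sample",
      "cloning host",
      "tissue",
      "whole organisms",
      "organoid",
      "technical sample"
    ],
    "SampleEnvironment": ["ex vivo", "in vivo", "in vitro"],
    "PixelSizeUnits": ["mm", "um", "nm"],
    "BodyPart": [
      "ABDOMEN",
      "ANKLE",
      "ARM",
      "BLADDER",
      "BRAIN",
      "BREAST",
      "CHEST",
      "EYE",
      "FOOT",
      "HAND",
      "HEAD",
      "HEART",
      "KIDNEY",
      "KNEE",
      "LIVER",
      "LUNG",
      "NECK",
      "PANCREAS",
      "PELVIS",
      "PROSTATE",
      "SHOULDER",
      "SKULL",
      "SPINE",
      "SPLEEN",
      "STOMACH",
      "THYROID",
      "UTERUS"
    ]
  }
}
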