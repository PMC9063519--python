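# Controlled vocabularies (registry 1.7.0)

## BodyPart

- ABDOMEN
- ANKLE
- ARM
- BLADDER
- BRAIN
- BREAST
- CHEST
- EYE
- FOOT
- HAND
- HEAD
- HEART
- KIDNEY
- KNEE
- LIVER
- LUNG
- NECK
- PANCREAS
- PELVIS
- PROSTATE
- SHOULDER
- SKULL
- SPINE
- SPLEEN
- STOMACH
- THYROID
- UTERUS

## PixelSizeUnits

- mm
- um
- nm

## SampleEnvironment

- ex vivo
- in vivo
- in vitro

## sample_type

- cell line
- in vitro differentiated cells
- primary cell
- cell-free sample
- cloning host
- tissue
- whole organisms
- organoid
- technical sample
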