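# micr-bids

A toolkit for **Microscopy-BIDS**, the microscopy extension of the Brain
Imaging Data Structure (BIDS 1.7.0). It is aimed at researchers and data
curators who organize optical, electron, or micro-CT microscopy datasets —
2D slides and 3D volumes, *ex vivo* or *in vivo* — as predictable BIDS trees
for sharing and archiving.

The package provides three things:

1. **A dataset validator.** Microscopy data files follow the entity grammar

   ```
   sub-<label>[_ses-<label>]_sample-<label>[_acq-<label>][_stain-<label>]
       [_run-<index>][_chunk-<index>]_<suffix>.<extension>
   ```

   with 17 registered modality suffixes (TEM, SEM, uCT, BF, DF, PC, DIC,
   FLUO, CONF, PLI, CARS, 2PE, MPE, SR, NLO, OCT, SPIM), three file-format
   families (PNG, TIFF, OME-TIFF), and files placed under
   `sub-<label>/[ses-<label>/]micr/`. The validator checks the grammar and
   placement, the `samples.tsv` / `participants.tsv` tables (mandatory
   `sample_type`, acyclic `derived_from`, animal metadata `species`,
   `strain`, `strain_rrid`), JSON sidecars merged under the BIDS Inheritance
   Principle against four metadata categories (Device Hardware, Image
   Acquisition, Sample, Chunk Transformations) with controlled
   vocabularies, and the consistency of sidecar `PixelSize` with embedded
   OME-XML headers. Findings come back as a deterministic report of
   symbolic issue codes (see `docs/registry/issue_codes.md`).

2. **A chunk-mosaic reconstruction engine.** When one physical sample is
   imaged as several chunks (fields of view), each chunk's sidecar carries a
   homogeneous affine `ChunkTransformationMatrix` restricted to per-axis
   scaling `s` and translation `t`,

   ```
   x' = s ⊙ x + t        (v' = M · [v, 1]ᵀ, bottom row [0, …, 0, 1])
   ```

   over the axes named by `ChunkTransformationMatrixAxis`. The engine
   validates matrices, maps pixel-center coordinates into the sample's
   common space, and stitches chunks into a full image or volume with
   `mean` or `last` overlap policies and an explicit coverage mask.

3. **A synthetic fixture generator.** Two templates (`png2d`,
   `ometiff3d`) write tiny, fully valid datasets — including minimal
   OME-XML headers — entirely from code, plus a catalogue of 26
   single-defect mutations, each mapped to exactly one validator issue
   code. No external downloads are needed to exercise every rule.

## Worked example

```bash
$ micr-bids init demo --template ometiff3d --seed 0
wrote 15 files under demo

$ micr-bids validate demo
0 errors, 0 warnings

$ micr-bids stitch demo --sub 01 --sample A --suffix SPIM -o mosaic.ome.tif
wrote mosaic.ome.tif: 4x16x16 mosaic, 1024/1024 pixels covered
```

The template writes one subject with one sample imaged as four 8×8×4 SPIM
chunks on a 2×2 grid; the `stitch` command reads their transformation
matrices and reassembles the 16×16×4 volume, reporting that every output
voxel was covered by exactly one chunk. Breaking the dataset on purpose is
equally scriptable:

```bash
$ python -c "from micr_bids import mutate_dataset; mutate_dataset('demo', 'pixel_size_mismatch')"
$ micr-bids validate demo
ERRORS:
  [E_PIXELSIZE_MISMATCH] sub-01/micr/sub-01_sample-A_chunk-01_SPIM.ome.tif: axis X: sidecar 1.0 um vs OME header 0.5 um
  [E_PIXELSIZE_MISMATCH] sub-01/micr/sub-01_sample-A_chunk-01_SPIM.ome.tif: axis Y: sidecar 1.0 um vs OME header 0.5 um
  ...
12 errors, 0 warnings
```

`micr-bids inspect <file>` parses a single filename, and
`micr-bids validate --strict --json` emits a machine-readable report that
also surfaces missing recommended metadata.

The two published "real-world" Microscopy-BIDS datasets (SEM and SPIM
based) are external downloads and are not part of the test inputs;
validating them cleanly is a stretch goal.

## Documentation

`docs/methods.md` describes the validation model, coordinate conventions,
and design decisions. `docs/registry/` holds tables of the shipped rules
(suffixes, formats, metadata fields, vocabularies, issue codes), generated
directly from the registry by `micr_bids.docgen`.
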