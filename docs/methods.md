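# Methods

This note documents what the toolkit implements, the conventions it fixes
where the Microscopy-BIDS data structure leaves room, and what its synthetic
fixtures do and do not demonstrate about real datasets.

## The validation model

A Microscopy-BIDS dataset is a directory tree: `dataset_description.json`,
the tables `samples.tsv` (required once sample entities exist) and
`participants.tsv` (recommended), and per-subject `micr/` directories
holding image files with JSON sidecars. Validation is a pure function of
the tree: the walk is sorted, findings are deduplicated and ordered by
(path, code, message), and two runs produce byte-identical JSON reports.
Pixel data is never decoded; the only binary read is the OME-XML header in
the first IFD of OME-TIFF files. This keeps validation fast and focused on
structure and metadata rather than image content.

Every finding is an issue code with exactly one severity (the catalogue is
in `micr_bids.issues` and rendered in `docs/registry/issue_codes.md`).
Files whose path contradicts their filename entities, and files whose
sidecar chain contains malformed JSON, are reported once and then excluded
from downstream cross-checks; otherwise a single root cause would cascade
into a pile of misleading secondary findings (missing-table-row errors for
a mislabeled file, missing-field errors for an unparseable sidecar).

### Filename grammar

Entities are `key-value` tokens in the fixed canonical order
`sub, ses, sample, acq, stain, run, chunk` — the upstream entity-table
order, since examples alone do not pin an order down. Labels are
case-sensitive `[A-Za-z0-9]+` (cross-platform filesystem safety); `run` and
`chunk` take decimal indices with any zero-padding width. Index identity is
the string as written; mixed widths within one sample+suffix group raise
the warning `W_PAD_INCONSISTENT` rather than an error. The two-part
extensions `.ome.tif` / `.ome.btf` are matched atomically before the
generic one-dot rule. `run` and `chunk` are accepted independently of each
other. The grammar is deliberately total: any single separator flip in a
valid name fails to parse rather than parsing as something else, a property
the test suite checks exhaustively per name.

### Tables

The TSV dialect is UTF-8, tab-separated, header first, `n/a` for missing.
Structural defects (ragged rows, duplicate or empty header names) are a
single `E_TSV_MALFORMED` finding; the reader is intentionally strict and
hand-rolled because off-the-shelf table readers silently repair exactly the
defects a validator must report. `sample_type` values come from the
ENCODE-derived biosample-type vocabulary (a superset of the commonly cited
"tissue" / "primary cell" / "cell-free sample"). `derived_from` references
are resolved within one participant — a slice derives from that animal's
block, not another animal's — so cross-participant references are
`E_DERIVED_FROM_UNKNOWN`, and exactly the members of a reference cycle are
flagged `E_DERIVED_FROM_CYCLE`. The `species` check is a shape heuristic
(two lowercase words) rather than a taxonomy lookup: the toolkit runs
offline, and a wrong-but-binomial species is indistinguishable from a right
one without a database. `strain_rrid` must match `RRID:<token>`.

### Sidecars and requirement levels

Sidecars merge under the standard inheritance scope (dataset root, subject,
session, file directory), deeper and more entity-specific files overriding
shallower ones field by field; the merged document records its provenance.
A candidate sidecar whose entities are a superset of the data file's is an
error (`E_SIDECAR_ENTITY_SUPERSET`), while one whose entity values simply
differ belongs to another file and is skipped silently.

The upstream extension marks almost every metadata field "recommended".
As a toolkit policy, `PixelSize` and its companion `PixelSizeUnits`
(vocabulary `mm`/`um`/`nm`) are **required** here: without them no spatial
interpretation, OME cross-check, or stitching is possible. All other named
fields are recommended; missing recommended fields surface only under
`--strict`. Unknown fields pass silently — the data structure is a floor,
not a ceiling. Controlled vocabularies (`SampleEnvironment`, `BodyPart`
with a documented anatomical subset of the DICOM Body Part Examined terms)
are extensible through the validator configuration (`--vocab-extra`),
with unknown values treated as errors.

### OME header consistency

Duplicated metadata must agree, so where an OME-TIFF header declares
physical pixel sizes they are compared with the sidecar `PixelSize` after
converting both to micrometres. The mm/um/nm lattice converts by powers of
10^3, which is exact to double precision for the decimal values that occur
in practice; the default relative tolerance of 1e-4 therefore only absorbs
decimal-string round-trips while catching any real discrepancy. The
sidecar remains authoritative: absent header sizes are not findings, and
header parsing reads only the `Pixels` attributes of the OME-XML.

## Chunk transformations and stitching

The affine placement of a chunk is restricted to per-axis scaling and
translation; general affines are validated (with `W_NONAXIAL_TRANSFORM`)
but refused for reconstruction, because resampling under rotation or shear
is out of scope. Conventions the matrix alone does not fix, chosen once
and applied everywhere:

* **Pixel centers** sit at integer coordinates 0 … n−1 per axis; the matrix
  multiplies column vectors (`v' = M · [v, 1]ᵀ`).
* **Axis order**: data arrays are indexed in the order named by
  `ChunkTransformationMatrixAxis`, and matrix rows/columns follow the same
  order. On-disk arrays are row-major ([Z,]Y,X) and are transposed to the
  declared order when loaded.
* **Units**: the matrix maps pixel indices into a world space whose unit is
  the sidecar `PixelSize` unit per output pixel; the physical size of an
  output pixel is the chunk `PixelSize` scaled by the matrix's diagonal.

The output grid uses, per axis, the minimum absolute scale over all chunks
as pixel size, and spans the union of mapped pixel-center extents. Each
source pixel center maps to the nearest output pixel, ties to even — no
interpolation, by design, so integer layouts reproduce exactly and the
engine can be checked against a brute-force per-pixel scatter oracle for
strict equality. Overlaps combine as the arithmetic mean of contributors
(`mean`, order-invariant) or the last writer in input order (`last`;
within one chunk, C-order last wins when downscaling collapses source
pixels). Uncovered pixels take the caller's fill value, and a coverage
mask counts contributors per output pixel. Zero scales and mixed
axis orders or dimensionalities within one group are refused.

## The fixture generator

The generator emulates complete dataset trees end to end so that every
rule — positive and negative — can be exercised without downloads. Sizes
are chosen to be the smallest that still exercise each mechanism:

* `png2d`: 2 subjects × 2 samples of 16×16 8-bit BF PNGs (1 µm pixels),
  a root-level inherited sidecar plus per-file sidecars, the stain entity
  with `SampleStaining` on one subject, and tables with animal metadata and
  one `derived_from` link per subject.
* `ometiff3d`: 1 subject, 1 sample, 4 SPIM chunks of 8×8×4 voxels
  (0.5 µm), stored as OME-TIFF with synthesized minimal OME-XML and placed
  on a 2×2 XY grid by translation-only matrices in Z,Y,X order, so the
  stitched 16×16×4 volume has a closed-form expected array.

Pixel content is a deterministic linear gradient plus seeded integer noise;
the OME-XML is synthesized by the package itself (no writer UUIDs or
timestamps), so trees are byte-identical per seed. Each template stays far
under 1 MB. The mutation catalogue (26 defects) applies exactly one
minimal change per defect and is tested as a bijection: validating the
mutant yields the mapped issue code and no unrelated errors.

What the fixtures do **not** show: real microscopy content (no optics, no
noise model worth the name), large or tiled BigTIFF files, lossy
compression, multi-channel/time OME dimensions, or the messiness of
hand-curated trees. Passing the suite demonstrates that the rules are
implemented and internally consistent, not that any particular real-world
dataset is valid; the published SEM/SPIM datasets remain external.

## Numerical and degenerate-input choices

* Version comparison for `W_VERSION_PREDATES_MICROSCOPY` parses the first
  two numeric components of `BIDSVersion`; unparseable versions are left
  alone (the missing-key error already covers the broken case).
* `round`/`np.rint` ties-to-even is used consistently in both the engine
  and its oracle, so half-pixel ties cannot diverge between them.
* Empty chunk lists, non-2D/3D shapes, and name strings with directory
  separators raise `ValueError` early rather than producing findings: they
  are caller errors, not dataset defects.
* An empty directory is `E_NOT_A_DATASET` (no description file, no
  `sub-*` directories); hidden entries and `derivatives/` are skipped
  silently; non-microscopy data-type directories are noted with a warning
  and otherwise ignored — the toolkit validates only the microscopy
  portion of a mixed dataset.

## Known limitations

* OME-XML handling is minimal by design (Pixels sizes and physical sizes);
  channels, planes, and 5D+ metadata are ignored.
* No OME-NGFF/Zarr support; no derivative datasets or processing-pipeline
  transformations; no registration or atlas coordinate systems.
* The BodyPart vocabulary ships as a subset of the DICOM terms; sites with
  other anatomy extend it via configuration rather than editing the
  registry.
* Stitching offers no blending, feathering, or intensity harmonization —
  overlap handling is exactly the two documented policies.
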