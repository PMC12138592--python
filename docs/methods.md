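# Methods

## Problem and model

`ligoverlay` assembles a comparative binding-site view from a series of
ligand-bound structures of the same protein. Each entry is treated as a
rigid body: the biological signal of interest is *where ligands sit
relative to a common protein frame*, not conformational change, so the
pipeline is built from rigid-body superposition, crystallographic symmetry
expansion, distance-based truncation, and density-fragment resampling.

## Superposition

The reference is always a single protein chain. Correspondence between a
mobile chain and the reference is a global sequence alignment on residue
identity (match +1, mismatch −1, linear gap −2, via Biopython's
`PairwiseAligner`); the rigid fit is the Kabsch SVD solution on
representative atoms (Cα for amino acids, C1′/P fallback for nucleotides,
first atom otherwise), with the smallest singular vector sign-corrected so
every returned rotation is proper (det +1, tolerance 1e−8).

The fit is refined by outlier rejection: after each fit, pairs whose
distance exceeds max(2·rmsd, 2.0 Å) are discarded; at most 5 cycles; never
below 3 pairs. The floor keeps the cutoff from collapsing on near-perfect
fits; the factor-2 rule is scale-free. These constants are this package's
own choice. The approach assumes the aligned chains share sequence — the
intended use case (one protein, many ligands, possibly several crystal
forms). It is *not* a sequence-independent structural aligner; distantly
related folds are out of scope.

Degenerate inputs: fewer than 3 aligned pairs raises a correspondence
error; collinear point sets (second singular value ≈ 0) raise a geometry
error rather than returning an arbitrary rotation.

## Symmetry mates and truncation

A ligand can be contacted by symmetry copies of the protein (lattice
contacts). Operators come from the Hermann–Mauguin symbol via gemmi's
space-group table; only Sohncke groups (all-proper operators) are accepted,
since chiral macromolecules cannot crystallize otherwise — anything else
fails loudly. The search enumerates every operator with lattice shifts in
−2..2 per axis (sufficient for any cell larger than the contact radius;
tests verify against a −3..3 brute force) and keeps residue copies with at
least one atom within the contact radius of any ligand atom. The contact
radius defaults to the truncation radius (4.5 Å): a mate only matters if it
would survive truncation.

Truncation keeps the ligand plus every residue — same chain, other chains,
waters, heteroatoms, symmetry copies — having ≥1 atom within 4.5 Å of a
ligand atom. Residues are kept or dropped whole. Waters are deliberately
included: ordered waters are part of the binding-site picture. Symmetry
copies land in fresh chains (lowercase letters then digits, deterministic
order). Models without cell/space-group metadata (e.g. cryoEM) skip the
symmetry step with a logged warning and truncate normally.

## Density

MTZ input must carry weighted 2Fo-Fc map coefficients labeled FWT/PHWT
(Refmac style) or 2FOFCWT/PH2FOFCWT (Phenix/Buster style); FWT/PHWT wins
when both exist. Anything else (e.g. only FP/SIGFP) is an unsupported
refinement output and errors with the column list.

Synthesis expands the coefficient set with the space-group operators
(F(hR) = F(h)·e^{−2πi h·t}) and Friedel mates, places the coefficients on
an FFT grid with spacing ≤ d_min/sample_rate (default sample_rate 3; below
2 is sub-Nyquist and rejected), and inverse-transforms one unit cell.
The map mean and RMS (σ) are computed over the full cell *before* any
extraction and travel with every fragment, so sigma-scaled fragments
(values′ = (v − μ)/σ) contour identically to the full map in a viewer;
they are also written into the CCP4 header's DMEAN/ARMS words. A constant
map cannot be sigma-scaled and raises a "flat map" error.

Fragment extraction returns the minimal axis-aligned subgrid containing
every point within the radius of the selection, wrapping periodically when
the parent covers a full cell; a request spanning more than one period
clamps to exactly one period anchored at the selection. Rigid
transformation resamples onto an axis-aligned grid in the reference frame
(trilinear interpolation at t⁻¹ of each node, step = smallest source step).
Nodes outside a non-periodic source become 0 and lower a reported coverage
fraction. One numerical subtlety: source coordinates are clipped to the
grid edge before interpolation, because scipy's constant-mode
`map_coordinates` zeroes coordinates an epsilon beyond the last node
instead of blending — without the clip, identity transforms lose their
boundary planes.

Mesh generation (contour 1 σ, carve 1.8 Å) is *display* metadata: the
emitted viewer script's `isomesh ... carve=` directive does the
triangulation, keeping the core headless.

## Input card

Line-oriented, whitespace-tokenized; `#REF path [chain]` only as the first
non-comment line (a later `#REF` is an error, chosen over silent
ignoring); `#G name` opens groups; entries are
`coords [map] chain resi|lo-hi name [align-chain]`. The optional map token
is recognized purely by extension (.mtz/.ccp4/.mrc/.map) — unambiguous in
practice and the only deterministic rule for a positional grammar with an
optional token. Residue ranges accept hyphen and en-dash. Unrecognized
`#` lines are comments. Relative paths resolve against the card file's
directory so cards can be shared. Serialization is the exact inverse of
parsing (property-tested round trip).

## Scene semantics

Reference precedence: an existing scene's reference, else the card's
`#REF`, else the first entry (its align chain or first chain). `reference`
and `map_objects` are reserved object names. Duplicate object names are
skipped with a notice, so re-running a grown card only adds new entries.
One failing entry is logged, recorded in the report, and does not abort
the run. Colors are drawn without replacement from a fixed ~20-name
palette with a seeded generator (recycling when exhausted); the mesh
inherits its object's color. Persistence is a re-runnable plain-command
viewer script plus standard-format files rather than a binary session —
headless, testable, and viewer-version-proof.

## Defaults

| Parameter | Default | Meaning |
|---|---|---|
| truncation radius | 4.5 Å | ligand-environment cutoff (also symmetry contact radius) |
| pipeline map radius | 3.0 Å | density fragment around the ligand |
| standalone extract radius | 9.0 Å | `extract-map` fragment |
| contour | 1.0 σ | mesh level, full-map sigma scale |
| carve | 1.8 Å | mesh masking distance around the ligand |
| sample_rate | 3.0 | synthesis grid spacing = d_min/3 |
| seed | 0 | color drawing and fixture generation |

All radii are exposed as flags; the defaults are the pipeline's reference
behavior.

## Synthetic fixtures

The fixture generator builds an ideal-geometry polyalanine helix (5 atoms
per residue, 2.3 Å helix radius, 100°/1.5 Å twist/rise) plus a one-residue
four-atom ligand inside a stated cell, with optional seeded coordinate
jitter and a rigid "mobile copy" motion. Structure factors use a Gaussian
point-atom model F(h) = Σ Z·e^{−B|h*|²/4}·e^{2πi h·x}, summed over
symmetry images — maps peak at atoms, which is what synthesis, extraction
and carving tests need. Default sizes (10 residues, 16×16×18 Å cell,
d_min 3 Å → ~360 reflections, ≤64³ grids) keep every fixture desk-scale.

What the fixtures do **not** emulate: form-factor tables, bulk solvent,
measurement noise, anomalous signal, alternate conformers, real ligand
chemistry. Passing tests therefore demonstrate the correctness of the
geometry, symmetry and Fourier machinery — not robustness to experimental
artifacts in real deposition data.

## Testing strategy

Every numerical operation is checked against an independent oracle:
applied transforms are recovered; sequence correspondence is compared to
an exhaustive monotone-matching enumeration on tiny chains; symmetry and
truncation are compared to a from-scratch brute force (own triplet parser,
own orthogonalization matrix, wider shift window); synthesis is compared
to direct Fourier summation and a Parseval variance identity; grid
transforms to index-shift/permutation oracles. The acceptance suite reruns
these at full study sizes (100 rigid motions, 50 random crystals across
five Sohncke groups, 200 random cards) plus a complete three-entry
pipeline run; `scripts/acceptance.py` recomputes the same quantities from
a command-line seed.

## Known limitations

* Single chain + integer residue range identifies a ligand; insertion
  codes, negative residue numbers and multi-chain ligands are unsupported.
* First model only; altlocs collapse to highest occupancy.
* No sequence-independent (CE/TM-class) alignment; chains must share
  sequence for correspondence.
* Polder/other difference maps are read as-is, never computed.
* Map fragments written for free (non-lattice) grids must be axis-aligned
  orthogonal; arbitrary oblique free grids are not representable in the
  CCP4 box convention used.
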