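# rootvox

Slice-tracking extraction of plant root systems from X-ray micro-CT image
stacks, with recovery of upward-growing (plagiotropic) laterals and
measurement of whole-system architectural traits.

A CT volume is treated as a stack of cross-sectional images. Starting from a
single user-supplied seed point on the top slice, a narrow-band level set
performs a local, appearance-driven segmentation of each slice, initialised
from the object(s) found on the previous slice. Each tracked object carries a
grey-level histogram (its appearance model) that adapts as root attenuation
drifts with depth; objects may split as the root branches. Because a fixed
top-to-bottom traversal misses roots that grow upward, the tracker re-examines
the slice behind it after every step: material visible when approaching a
slice from below but absent from the forward labelling is recorded as a
*marker*. After the first full pass, markers are consumed lowest-first, each
spawning a pass in the opposite direction (which can in turn mark downward
roots hanging off upward segments), until no markers remain. Voxels remember
the direction of the pass that found them, which yields direction-aware traits
such as the upward-grown fraction of the root system.

## Modules

| module         | contents                                                              |
|----------------|-----------------------------------------------------------------------|
| `volume_io`    | TIFF/PNG stack I/O, segmentation artifacts, ascii PLY meshes, CSV logs |
| `segmentation` | appearance models, narrow-band level set, connected components         |
| `tracking`     | slice-to-slice advance, look-back markers, alternating-pass scheduler  |
| `traits`       | volume, iso-surface area, Welzl max-width, QuickHull + Monte Carlo hull volume, upward fraction, direction changes |
| `phantom`      | synthetic root-in-soil CT phantoms with voxel-level ground truth       |
| `cli`          | `simulate` / `track` / `measure` / `compare` commands                  |

## CLI

Generate a phantom, track it, and measure traits:

```sh
rootvox simulate --phantom-name one_upward_lateral --out scratch/sim --rng-seed 1
rootvox track --stack scratch/sim/grey.tif --seed-x 64 --seed-y 64 \
    --voxel-size-um 100 --out scratch/seg
rootvox measure --seg scratch/seg --voxel-size-um 100 --out scratch/traits.csv \
    --mesh scratch/root.ply
```

Compare a forward-only run against the full (look-back) run:

```sh
rootvox track --stack scratch/sim/grey.tif --seed-x 64 --seed-y 64 \
    --forward-only --out scratch/seg_fwd
rootvox compare --seg-a scratch/seg_fwd --seg-b scratch/seg --out scratch/cmp.csv
```

Key tracking flags: `--alpha` (data vs smoothness weight, default 0.6),
`--beta` (appearance-similarity threshold for model updates, default 0.25),
`--forward-only` (disable look-back, reproducing the plain top-to-bottom
tracker), `--min-area`. Every command writes a `manifest.json` recording all
parameters and seeds. Exit codes: 0 success, 2 bad input, 3 seed rejected.

## Conventions

- Stacks are indexed `(slice, row, col)`; slice 0 is the top of the soil
  column; directory stacks are read in lexicographic filename order.
- Voxels are isotropic; a voxel's centre is at `index * voxel_size`.
- Grey values are used as stored (8- or 16-bit); appearance histograms are
  binned over each stack's global min-max.
- All tracking is deterministic; the only randomness (Monte Carlo hull
  volume, Welzl shuffle) is seeded and the Welzl result is
  permutation-invariant.
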