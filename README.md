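# myoseg

Scriptable analysis of immunofluorescent skeletal-muscle cross-sections:
watershed-based fiber segmentation with h-minima smoothing, shape-based
fiber filtering, per-fiber morphometry (CSA, min/max Feret diameter),
fiber typing, centrally-nucleated-fiber (CNF) calling, and extra-fiber
object counting (e.g. capillaries).  All interactive editing steps are
replaced by file-driven inputs (JSON separation strokes, removal-id lists,
threshold flags), and a synthetic section generator with exact ground
truth makes every stage testable without slide images.

## Library overview

| Module | Role |
| --- | --- |
| `myoseg.image_io` | images, label masks (TIFF), parameter files, tables |
| `myoseg.segmentation` | minima suppression, watershed, separation strokes, overlays |
| `myoseg.fiber_filter` | edge/area/eccentricity/convexity filtering, manual removal |
| `myoseg.morphometry` | centroids, Feret diameters (rotating calipers), summaries |
| `myoseg.fiber_typing` | per-fiber mean intensity, Otsu threshold, positive/negative calls |
| `myoseg.central_nuclei` | border-distance erosion, nuclear detection, CNF calls |
| `myoseg.object_counter` | smoothing + Otsu + connected components |
| `myoseg.synthetic` | Lloyd-relaxed Voronoi sections with ground truth |

Conventions: 8-connected basins and components throughout; ridge pixels
belong to no fiber (label 0); shape measures (convexity, Feret) use the
convex hull of pixel corners so convex rasters score exactly 1 and a
w-pixel bar has min Feret exactly w; channel indices are 1-based (1=red,
2=green, 3=blue) at the interface; coordinates are 0-based with x=column,
y=row.

Default parameters (pixel size 0.645 μm/px, smoothing 5/5/10, fiber area
100-5000 μm², max eccentricity 0.95, min convexity 0.8, border distance
10 μm, min nuclear size 5 μm²) are built in; a plain-text `key = value`
file (or a two-column spreadsheet via `load_params_xlsx`) overrides them.

## CLI

```sh
# make a ground-truthed synthetic section
myoseg synth --seed 1 --outdir out

# full pipeline on any RGB section image
myoseg all out/synthetic_seed1.png --with-type --with-cnf --with-objects --outdir out

# or stage by stage, with manual edits between stages
myoseg segment img.png --smoothing 5 --strokes strokes.json --outdir out
myoseg filter img.png --min-area 100 --max-area 5000 --remove 12,31 --outdir out
myoseg props img.png --outdir out --xlsx
myoseg type img.png --threshold 80 --outdir out
myoseg cnf img.png --border-distance 10 --min-nuclear-size 5 --outdir out
myoseg objects img.png --outdir out
```

Outputs per image: `<stem>_mask.tif`, `<stem>_Props.csv`,
`<stem>_FiberType.csv`, `<stem>_CNF.csv`, `<stem>_Objects.csv` (plus
`.xlsx` with `--xlsx`), overlay/histogram PNGs, and a
`<stem>_<cmd>_log.json` recording every parameter actually used,
including auto-selected Otsu thresholds — re-run with `--threshold` to
adjust.  Analysis commands require the mask from `segment` and say so if
it is missing.

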