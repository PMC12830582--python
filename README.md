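# dcshape

Label-free image analysis for deformability cytometry (DC).

Deformability cytometry streams brightfield images of single cells as
shear forces deform them in a microfluidic constriction, at hundreds of
frames per second in 8-bit grayscale. The raw product is a sequence of
frames containing not only intact cells but also anomalous cells, dead
cells, cell aggregates and debris. `dcshape` turns those frames into
per-cell morphometry and gate-free population statistics:

- **Segmentation** — temporal-median background subtraction, Gaussian
  filtering, fixed-offset thresholding and morphological cleanup, then
  sub-pixel contour extraction for every detected event.
- **Morphometry** — projected area *A*, contour perimeter *l*, and the
  isoperimetric deformation

  $$D = 1 - \frac{2\sqrt{\pi A}}{l}$$

  which is 0 for a circle and grows with elongation or boundary
  irregularity. Sample locations are summarised by the mode of a
  Gaussian kernel density estimate rather than by binning.
- **Event classification** — a five-class convolutional network
  (intact / anomalous / dead / aggregate / debris) replaces manual
  gating. Training uses inverse-frequency class weights, stratified
  80/20 splits, augmentation, early stopping and learning-rate
  reduction on plateau. The network stack is implemented in numpy and
  trains on a single CPU core at desk scale.
- **Lipid-droplet counting** — dark cytoplasmic inclusions are counted
  per cell by relative thresholding inside the rim-eroded cell mask,
  giving a label-free readout of intracellular lipid accumulation.
- **Synthetic data** — a frame generator renders all five event
  classes with exact polygon ground truth, known droplet counts and a
  tunable intact-vs-anomalous difficulty, so every stage can be
  validated without instrument data.

An HDF5 event store (crops, masks, contours, aligned feature columns)
connects the stages, in the spirit of the community `.rtdc` layout.

## Worked example

```python
import numpy as np
from dcshape import synthgen, segment, morpho
from dcshape.events import EventClass

specs = synthgen.random_frame_specs(
    n_frames=10, objects_per_frame=3,
    class_probs={EventClass.INTACT: 0.7, EventClass.DEAD: 0.3},
    seed=7, droplet_range=(0, 3), width=384, height=128)
frames, truth = synthgen.generate_frames(specs, seed=8)

events = segment.segment_frames(frames)
features = [morpho.compute_event_features(e, pixel_size_um=0.147)
            for e in events]
print(f"{len(events)} events from {len(truth)} planted objects")
for f in features[:3]:
    print(f"A = {f.A_um2:6.1f} um^2   l = {f.l_px:6.1f} px   "
          f"D = {f.D:.4f}   aspect = {f.aspect_ratio:.2f}")
mode = morpho.estimate_mode([f.D for f in features])
print(f"mode deformation = {mode.mode:.4f} (n = {mode.n})")
```

prints

```
29 events from 30 planted objects
A =    3.6 um^2   l =   46.3 px   D = 0.0133   aspect = 1.08
A =   26.6 um^2   l =  125.3 px   D = 0.0079   aspect = 1.20
A =   38.9 um^2   l =  151.8 px   D = 0.0094   aspect = 1.20
mode deformation = 0.0072 (n = 29)
```

The one missed object is a low-contrast dead cell that fell below the
default detection threshold; the detected events are nearly circular
at rest (D close to 0), as expected for undeformed cells. Deformations here carry only
digitisation noise — the generator plants circular-to-elliptical
objects, and the sub-pixel contour keeps the bias of a digitised disk
below 0.002.

## Command-line pipeline

The same stages run end-to-end from one YAML configuration:

```sh
dcshape simulate  --config run.yaml   # frames + ground truth + crops
dcshape segment   --config run.yaml   # event store
dcshape features  --config run.yaml   # A, l, D, ... + CSV export
dcshape train     --config run.yaml   # classifier weights + manifest
dcshape classify  --config run.yaml   # labels into the store
dcshape droplets  --config run.yaml   # droplet counts into the store
dcshape report    --config run.yaml   # summary JSON/CSV + 2-D histogram
```

Every command is idempotent given the same config and seed; reruns are
byte-identical (outputs carry a config hash instead of timestamps).

## Layout

```
src/dcshape/
  events.py     # EventClass, EventRecord, SampleSummary
  synthgen.py   # synthetic frames, ground truth, labelled crops
  imgio.py      # frame reading, HDF5 event store, CSV export
  segment.py    # background model, detection, sub-pixel contours
  morpho.py     # area / perimeter / deformation, KDE mode, summaries
  nn.py         # numpy conv-net stack (im2col, batchnorm, Adam)
  classify.py   # five-class CNN: split, weights, train, predict
  droplets.py   # lipid-droplet counting
  cli.py        # dcshape <stage> --config run.yaml
docs/methods.md # model assumptions, parameters, limitations
```

See `docs/methods.md` for the scientific rationale behind each design
choice and the known limitations of the synthetic benchmark.
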