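# dinosarc

Color-saliency feature extraction for wireless capsule endoscopy (WCE)
frames: detection of salient points and regions from chromatic information
alone, 9-dimensional local color descriptors, and Bag-of-Visual-Words
(BoVW) global descriptors, with an evaluation harness and a synthetic
frame generator so the whole pipeline can be exercised without clinical
data.

## The problem and the method

A capsule endoscope captures ~100k frames per examination; readers triage
them for abnormalities (vascular, inflammatory, polypoid lesions).
Abnormal tissue tends to occupy a small color range at the *margins* of
each frame's own chromatic range — but those ranges shift from frame to
frame, so no fixed color threshold separates the classes across a dataset.

Working in CIE-Lab, with `a` (green↔red) and `b` (blue↔yellow) giving an
approximately illumination-invariant description of color, the pipeline
is:

1. **SARC** (Selective Aggregation of chRomatic image Components).
   For each chromatic component `c ∈ {a, b}`, form the normalized
   histogram `H_c` over the field-of-view, split it at zero, and walk each
   half-axis outward. The first derivative `r_c` and second derivative
   `R_c` of each half-axis sequence are computed, and the threshold
   `T_c^±` is placed at `argmax R_c` — the outer foot of the normal lump,
   where the rate of decline changes and abnormal mass begins.
   Thresholding yields four component images (a+, a−, b+, b−), each
   filtered by an `n × n` sliding window that discards local non-maxima;
   their sum is the saliency map `I_SARC`.
2. **DINOSARC points.** Each nonzero pixel of `I_SARC` is scored by the
   Euclidean distance, in the (a, b) plane, between the chromatic maxima
   and minima sampled over concentric `s × s` and `s/2 × s/2` windows
   (default `s = 10`). Points scoring at least τ (default: the per-image
   mean candidate score) are salient.
3. **Salient regions.** The frame is oversegmented with SLIC; every
   superpixel containing a salient point is a salient region, reduced to a
   single representative point (cluster centroid), so abnormalities
   smaller than a superpixel stay localized.
4. **Descriptors.** Each salient region yields the 9-vector
   `[L_p, a_p, b_p, min L, max L, min a, max a, min b, max b]` (point
   values plus regional extrema). A k-means visual vocabulary quantizes
   descriptors into words; the normalized word histogram is the global
   image descriptor.
5. **Evaluation.** Detector quality is measured by false-negative images
   (abnormal frames with no point on the lesion) and the true-positive
   point fraction; classification uses 10-fold stratified cross-validation
   with an RBF-SVM and ROC/AUC analysis.

## Worked example

```python
from dinosarc import (SynthConfig, generate_frame, sarc_map, detect,
                      DetectorParams, slic_segment, salient_regions,
                      local_descriptor)

frame = generate_frame(SynthConfig(lesion_kind="positive_a", seed=3))
img = frame.to_lab()
sal = sarc_map(img)
pts = detect(img, sal, DetectorParams(window_s=10))
seg = slic_segment(img)
regs = salient_regions(seg, pts)
```

On this 360 × 360 frame with a reddish lesion planted beyond the
background's `a` range, the pipeline prints:

```
thresholds: a+ 7.0, a- -7.0, b+ 6.0, b- -7.0
candidate pixels: 491
salient points: 194; strongest score 17.92 at (72, 181)
points inside the true lesion: 8
salient regions: 72 (from 200 superpixels)
top-region descriptor: [42.2, 16.08, 1.29, 40.55, 52.92, 0.55, 17.42, -0.41, 5.58]
lesion truth: background a max 4.92, lesion a min 12.42
```

The data-driven threshold `T_a^+ = 7.0` lands strictly between the
background maximum (4.92) and the lesion minimum (12.42): the saliency map
isolates the planted abnormality. The strongest salient point sits on the
lesion, and the top region's descriptor shows the diagnostic signature —
a point `a` value (16.08) and regional `max a` (17.42) far above the
regional `min a` (0.55).

The same stages are available from the shell:

```bash
dinosarc synth --n-abnormal 2 --n-normal 1 --seed 7 --out data/
dinosarc sarc --in data/frame_0000.png --out map.png
dinosarc detect --in data/frame_0000.png --out points.csv
dinosarc run --synth-frames 10 --out run_out/
```

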