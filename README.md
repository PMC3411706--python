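# vqmouse

Quantitative ventilation/perfusion (V/Q) SPECT/CT analysis for the mouse
lung.

Regional gas exchange depends on how well alveolar ventilation (V) and
pulmonary capillary perfusion (Q) are matched. In small-animal imaging
this is measured by ventilating the animal with a ⁹⁹ᵐTc-labelled aerosol
(Technegas), injecting ⁹⁹ᵐTc-MAA to trap in the pulmonary capillaries,
and acquiring SPECT/CT for each process. After co-registration, every
lung voxel carries a V, Q, HU and log₁₀(V/Q) value, and the shape of the
log(V/Q) distribution quantifies V/Q matching — its mean sits near the
physiological optimum (log₁₀ 0.80 ≈ −0.097 in humans), its spread and
tails measure heterogeneity and mismatch.

`vqmouse` implements that analysis chain for people who build or evaluate
preclinical lung-function pipelines:

* **CT lung segmentation** — a −50 HU threshold-limited region growing,
  bounded volume growing gated at +100 HU, 3-D hole filling (vessels
  belong to the lung), and trachea/main-bronchi removal for the
  ventilation label.
* **Mutual-information rigid registration** — Powell's direction-set
  method over the 6 rigid parameters, golden-section/parabolic line
  searches, stop criteria of 0.01 mm / 0.01°, MI evaluated within the
  lung label from a Parzen-smoothed joint histogram with partial-volume
  interpolation. The study flow fuses the perfusion SPECT to its CT,
  transfers that transform to the ventilation pair, co-registers the two
  CTs, and composes the maps so V and Q meet on one grid.
* **Per-voxel log(V/Q) quantitation** — activities normalized to relative
  frequencies (% of label total, so the ~24:1 perfusion:ventilation
  activity ratio cancels), voxels with V = 0 → −∞, Q = 0 → +∞, both → a
  noted zero; mean/SD/skewness/excess kurtosis over finite voxels; V/Q
  mismatch as % of total lung volume beyond ±2 reference SD; per-voxel
  V–Q Pearson correlation.
* **Regionalization** — apex/middle/base thirds at the 33 %/66 % volume
  percentiles, and inner/outer shells by 3-voxel six-neighbour erosion.
* **CT densitometry and air volumes** — 25 HU/bin histograms with a
  clamped-linear air coefficient (−500 HU → 0.5), FRC from the
  end-expiratory gated CT, tidal volume as inspiratory − expiratory air.
* **A digital mouse-thorax phantom** — generates CT + coupled V/Q SPECT
  volumes with known lung label, known rigid misalignments, controllable
  log(V/Q) mean/SD, zero-activity defect fractions, V–Q correlation and
  air volumes, so the whole pipeline is testable without scanner data.

## Worked example

```python
import vqmouse as vq

spec = vq.PhantomSpec(seed=1)          # healthy-mouse study conditions
bundle = vq.generate_phantom(spec)
label = bundle.label

v_rel = vq.normalize_activity(bundle.vent, label)
q_rel = vq.normalize_activity(bundle.perf, label)
res = vq.compute_log_vq(v_rel, q_rel, label)
summ = vq.summarize(res, vq.ReferenceStats(-0.071, 0.361))
frc, tv = vq.frc_tv(bundle.ct_exp, bundle.ct_insp, bundle.truth.thorax_roi)
```

prints, when the fields above are formatted:

```
lung volume        : 0.562 mL (46208 voxels)
log(V/Q) mean      : -0.0710  (V/Q ratio 0.85)
log(V/Q) SD        : 0.3610
-inf / +inf %TLV   : 3.23 / 0.0022
low / high mismatch: 5.61 / 2.05 %TLV
V-Q Pearson R      : 0.580
FRC / TV           : 0.1240 / 0.0480 mL
```

Reading: the mean log(V/Q) of −0.071 back-transforms to a V/Q ratio of
0.85 — slightly perfusion-rich, as in healthy lungs; the SD of 0.361
measures matching heterogeneity across ~46k voxels; 3.23 % of lung volume
is unventilated (V = 0, log(V/Q) = −∞) while essentially none is
unperfused; the air-coefficient method recovers a functional residual
capacity of 0.124 mL and a tidal volume of 0.048 mL from the gated CTs.

The same flow is scriptable from the shell:

```sh
vqmouse phantom --out ph/ --seed 1
vqmouse segment ph/ct_exp.nii.gz --out label.nii.gz --no-downsample
vqmouse vqstats --vent ph/vent.nii.gz --perf ph/perf.nii.gz \
    --label ph/label.nii.gz --out summary.json --hist hist.tsv
vqmouse run study.yaml        # manifest-driven end-to-end run
```

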