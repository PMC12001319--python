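# ddlseg — prior-guided deep difference learning for contouring styles

Auto-segmentation models for radiotherapy are trained on anatomical
structure definitions, but clinics contour in *styles*: a target volume
capped 1 cm into the bladder, a parotid contoured only on its superficial
lobe, a rectum contoured only on slices that contain the prostate.  When a
pre-trained "general" model is deployed at a new institution, its output
must be adapted to the local style — classically by collecting data and
fine-tuning, which small clinics often cannot do.

`ddlseg` implements a meta-learned alternative: a **prior-guided deep
difference learner**.  The idea is that a style is a *systematic
difference* between the general model's output `M` and the approved
contour `P`, and that this difference can be read off a handful of
already-corrected "prior" patients and applied to a new patient **without
any parameter updates**.

## The model

A shared 3D encoder `f(·)` ingests (image, mask) pairs as 2-channel
volumes.  Per resolution level it applies a 3×3×3 convolution, ReLU,
group normalization (32 features per group) and three parallel atrous
convolutions (dilation rates 6, 12, 24, summed), followed by 2× max
pooling; with base width F the pyramid carries F, 2F and 4F channels.
The style of n prior patients is summarized in feature space by the
difference block

    DDL({P_i}, {M_i}) = (1/n) Σ_i tanh( Conv3D_θ( f(P_i) − f(M_i) ) )

at the deepest level.  A decoder concatenates this style signal with the
query patient's deepest features and upsamples back to a voxel-wise
sigmoid probability, merging the query's skip features on the way.  With
zero priors the style signal is a zero grid — the *no-adaptation
baseline*.

Meta-training is episodic: each iteration draws a simulated style, a
support count k ~ U{1..10} and k+1 subjects; the query's styled contour
is the target of a combined soft-Dice + Hausdorff-surrogate loss (the
boundary term's weight ramps up once the running Dice clears 0.70), and
encoder, difference block and decoder are updated jointly with Adam
(lr 10⁻³, batch size 1).  Held-out styles are *never* drawn during
training, so evaluation measures adaptation to genuinely unseen styles.

Because clinical CT/contour data are private, the package ships a seeded
**phantom generator**: deformed-ellipsoid anatomies with five structures
(a target, superior and posterior neighbors it overlaps, and two
slice-landmark references), a simulated general model calibrated to
≈ 0.85 mean Dice against truth, and a library of 16 training + 4 held-out
style transforms built from composable mask operators (dilate/erode,
slice conditioning, fixed-depth extension/capping, aspect splits).  The
whole train → adapt → evaluate cycle therefore runs anywhere, with no
external data, on one CPU — the network stack is a small numpy
reverse-mode autodiff engine (`ddlseg.autograd`), gradient-checked
against finite differences.

## Worked example

```python
from ddlseg.model import PriorGuidedDDL
from ddlseg.meta_training import TrainConfig
from ddlseg.phantom import generate_cohort

model = PriorGuidedDDL.from_phantoms(n_subjects=40, seed=100,
                                     config=TrainConfig(iterations=1500, seed=1))
res = model.fit()            # ~12 min on one CPU
print(res.summary())

curve = res.sweep_priors("test_superior_half",          # a held-out style
                         generate_cohort(8, seed=900),  # test patients
                         generate_cohort(10, seed=950)) # prior patients
print(curve.summary.round(3))
```

Output of the sweep on the reference run (seed 1):

```
   n_priors  mean_dsc  sd_dsc  mean_hd  sd_hd  n_subjects
0         0     0.542   0.055   10.500  1.323           8
1         1     0.741   0.093    2.800  0.660           8
2         3     0.766   0.068    3.048  0.678           8
3         5     0.765   0.071    3.048  0.678           8
4        10     0.758   0.076    2.918  0.768           8
```

Reading: with **zero** priors the meta-learner does not know the local
style ("superior half of the structure only") and scores a mean Dice of
0.54 against the styled truth; **one** corrected example patient lifts it
to 0.74, three to 0.77, with the Hausdorff distance falling from 10.5 mm
to about 3 mm — and the model's weights never change during adaptation.
This mirrors the clinical workflow: the first corrected patient already
buys most of the improvement, and the curve saturates after a few priors.

The same objects drive the CLI:

```bash
ddl phantom --n 20 --seed 3 --out data/
ddl train --out run/                      # reference config by default
ddl sweep --checkpoint run/checkpoint.npz --data data/ \
    --style test_superior_half --n 0,1,3,5,10 --out curve.csv
ddl adapt --checkpoint run/checkpoint.npz --priors data/ \
    --style test_superior_half --query-image q_image.nii.gz \
    --query-general q_general.nii.gz --out styled.nii.gz
```

## Layout

| module | contents |
| --- | --- |
| `ddlseg.grids` | `Volume`, `Mask`, `StructureSet`, `PhantomSubject` containers |
| `ddlseg.phantom` | seeded anatomy generator + simulated general model |
| `ddlseg.style_ops` | composable mask operators and the style preset library |
| `ddlseg.metrics` | DSC, Hausdorff (mm), soft-Dice and Hausdorff-surrogate losses |
| `ddlseg.autograd` | minimal reverse-mode engine (3D conv, group norm, pooling, …) |
| `ddlseg.network` | encoder, difference block, decoder; `ModelState` + digests |
| `ddlseg.meta_training` | episodic training loop (`TrainConfig`, `train`) |
| `ddlseg.adaptation` | prior banks, workflow simulation, sweeps, transfer baseline |
| `ddlseg.model` | `PriorGuidedDDL` / `DDLResults` fitted-model facade |
| `ddlseg.io`, `ddlseg.cli` | NIfTI + checkpoint formats, the `ddl` command |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
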