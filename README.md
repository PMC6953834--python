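# ioertdose

Dose-scenario comparison for intraoperative electron radiation therapy (IOERT)
from paired pre- and intraoperative CT studies.

## The problem

In IOERT, a rigid PMMA applicator collimates a single-fraction electron beam
onto a surgically exposed tumour bed. Beam energy is chosen under the
*conventional assumption* of a flat, water-equivalent irradiation surface at
the applicator end. The real surgical field violates this in two ways: an
**air gap** between the applicator's (possibly beveled) exit face and the
irregular resection surface, and **tissue heterogeneity**. This package
quantifies how much each factor matters by building five CT scenarios on a
common 1.5 mm grid and gamma-comparing their 3D dose distributions against the
intraoperative gold standard `D_intraCT`:

* `D_preCT_water` — registered preoperative CT, water-equivalent tissue, flat
  water medium from the bevel plane (the conventional assumption);
* `D_preCT` — registered preoperative CT (heterogeneity, no air gap);
* `D_preCT_water&air` — water-equivalent tissue **plus** the segmented air gap;
* `D_preCT_air` — registered preoperative CT **plus** the segmented air gap.

Each is compared with `D_intraCT` using the 3D gamma index at 3%/3 mm, global
normalisation, for dose above 10% and above 70% of the reference maximum,
excluding voxels outside patient tissue:

    gamma(v) = min_u sqrt( (|u - v| / 3 mm)^2 + ((D_eval(u) - D_ref(v)) / 3%)^2 )

and a voxel passes when gamma <= 1.

The toolkit covers the whole analysis: NIfTI/MetaImage I/O and isotropic
resampling; rigid registration of the preoperative to the intraoperative CT by
normalised mutual information restricted to segmented bone; region-growing
segmentation of bone, patient body, applicator wall and the air gap (below the
−500 HU limit, along the applicator's longitudinal extension); recovery of the
applicator pose (bevel centre, axis, roll) from the wall segmentation; the HU
edits that build the five scenarios; a deterministic divergent pencil-beam
electron dose engine with radiological depth (a pluggable stand-in for a Monte
Carlo engine); and the gamma analysis with an exhaustive brute-force oracle.
Because clinical CT pairs are not shipped, a seeded phantom generator produces
paired studies with exact ground truth (pose, motion, air gap, tissue masks);
see `docs/methods.md`.

## Worked example

```python
from ioertdose import CaseConfig, PhantomConfig, run_case

cfg = CaseConfig(phantom=PhantomConfig(seed=11, target_max_gap_mm=30.5))
report = run_case(cfg)
print(report.to_frame().to_string(index=False))
print("RMS HU:", round(report.rms_hu, 1),
      " max air gap:", round(report.max_air_gap_mm, 2), "mm")
```

prints (a 7 cm, 30°-bevel applicator at 9 MeV over a tumour bed with a
30.5 mm maximum air gap):

```
               comparison  Dose > 10%  Dose > 70%    Average
    intraCT v preCT_water   44.680291   37.297159  40.988725
          intraCT v preCT   51.921874   45.302625  48.612250
intraCT v preCT_water_air  100.000000  100.000000 100.000000
      intraCT v preCT_air  100.000000  100.000000 100.000000
RMS HU: 84.0  max air gap: 29.33 mm
```

Reading it: with a 30.5 mm air gap, the conventional water assumption
(`preCT_water`) agrees with the intraoperative gold standard at only ~41% of
analysed voxels, and adding tissue heterogeneity alone (`preCT`) barely helps —
but once the segmented air gap is written into either scenario the agreement
jumps to ~100%. The air gap, not heterogeneity, drives the disagreement. The
RMS HU difference between the registered preoperative and intraoperative
images over tissue in the dose region (84 HU here) summarises residual
anatomical mismatch; the measured maximum air-gap distance (29.3 mm) is the
largest distance from the applicator end to the tumour-bed surface along the
beam axis.

The same pipeline is scriptable from the shell:

```bash
ioert phantom --out case/ --seed 11
ioert run --config case.yaml --out results/
ioert gamma --ref dose_intraCT.nii.gz --eval dose_preCT_water.nii.gz \
            --tissue-mask body.nii.gz --dd 3 --dta 3 --threshold 10
```

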