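# cliviplan

Risk-weighted corridor planning for surgery of the **inferior clivus** — the
lowest part of the clival bone, reached through the narrow retro-condylar
cleft between the medulla, the occipital condyle, the jugular tubercle and
the vertebrobasilar vessels.  The package is aimed at skull-base surgeons,
surgical educators and computational-anatomy researchers who want a fully
automated, individualized answer to the question *which corridor should this
anatomy be approached through?* — and a reproducible test bed for studying
how anatomical variation flips that answer.

## The model

Anatomy is a voxel **label map** (NIfTI, RAS, mm) over eight tissue classes
(free space, bone, cerebellum, brainstem, artery, vein, cranial nerve,
other) plus a set of named 3-D **landmarks**.  The corridor system is a
declarative graph:

* a **window** is a triangular aperture spanned by three landmarks;
* a **path** is a tetrahedral corridor segment spanned by four landmarks,
  entered and exited through two of its faces;
* a **plan** is a face-adjacent chain of paths from the posterolateral entry
  window to the clival target window.

Each path *p* is scored from the tissue inside its tetrahedron:

```
risk(p)    = Σ_c  V_c(p) · r_c          (injury risk, weighted mm³)
freedom(p) = V_space(p)                 (surgical freedom, mm³)
w(p)       = risk(p) − freedom(p)       (path weight; may be negative)
```

where `V_c` is the voxel-center volume of tissue class *c* inside the
tetrahedron and `r_c` a per-class risk coefficient (default: brainstem 5,
artery = cranial nerve 4, vein 3, cerebellum 2, bone = other 1, space 0).
The optimal plan minimizes `Σ w(p)` over all entry-to-target chains, found
by single-source shortest-path relaxation in topological order on the
window/path DAG (exact for the negative weights this model routinely
produces; an exhaustive enumerator is kept as an oracle).  Plans are
labelled by where their corridor runs relative to the jugular tubercle:
**ITA** (infra-), **TTA** (trans-) or **STA** (supra-tubercle).

The bundled default topology has 11 landmarks (`a`…`k`), 17 windows, 12
paths and exactly 7 plans; the TTA plan traverses the corridor segment
`cfij`.  A parametric phantom generator synthesises the retro-condylar
region (condyle, tubercle, foramen magnum rim, medulla, cerebellum,
vertebral artery + PICA/AICA, sigmoid sinus/jugular bulb, CN VI–XII) with
controllable variation: vertebral-artery caliber, sinus dominance, CN XI
height, bony prominence sizes and landmark jitter — so the whole pipeline
is testable without patient imaging.

## Worked example

Generate one synthetic subject, then plan it:

```bash
cliviplan phantom --seed 11 --out-labels lab.nii.gz --out-landmarks lm.json
cliviplan plan --labels lab.nii.gz --landmarks lm.json \
               --out report.json --csv summary.csv
```

The plan command prints the winner and writes a ranked summary:

```
{"plan_id": "var-ed", "approach_label": "ITA", "total_weight": -3405.0}
```

```
plan_id,label,total_weight,injury_risk_sum,freedom_sum,rank
var-ed,ITA,-3405.000000,7273.000000,10678.000000,1
var-edf,TTA,-3347.000000,6076.000000,9423.000000,2
ita,ITA,-3255.000000,7203.000000,10458.000000,3
var-df,TTA,-3197.000000,6006.000000,9203.000000,4
var-e,ITA,-2555.000000,6830.000000,9385.000000,5
tta,TTA,-2497.000000,5633.000000,8130.000000,6
sta,STA,-560.000000,10932.000000,11492.000000,7
```

For this subject the infra-tubercle route wins: its corridors buy 10 678 mm³
of operative freedom at 7 273 weighted-mm³ of tissue risk, a net weight of
−3 405, ahead of the best trans-tubercle chain by 58.  The supra-tubercle
plan is last — its high corridor crosses cerebellum and the sigmoid–jugular
venous system.  Dilate the vertebral artery, which threads the infra
corridors, and the decision flips:

```bash
cliviplan sweep --parameter va_radius_mm --grid 0.8,1.5,2.5,3.5,4.5 --out sweep.csv
```

```
 va_radius_mm winner_plan winner_label
          0.8      var-ed          ITA
          1.5      var-ed          ITA
          2.5      var-ed          ITA
          3.5     var-edf          TTA
          4.5     var-edf          TTA
```

A cohort of 50 synthetic subjects under the bundled (frozen-seed) variation
distribution tabulates how often each approach is optimal:

```bash
cliviplan cohort --n 50 --out cohort.json
# {"ITA": {"count": 39, "percent": 78.0}, "STA": {"count": 4, "percent": 8.0},
#  "TTA": {"count": 7, "percent": 14.0}}
```

ITA is modal, STA rare — the ordinal pattern expected from screening real
anatomies (the exact percentages of a patient series depend on real anatomy
and are not a target of the phantom cohort).

Exact evaluation statistics are also exposed:

```bash
cliviplan stats fisher --table 56 6 62 0
# {"p_value": 0.027533246719366782}
```

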