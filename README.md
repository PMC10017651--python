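# lungshrink

Quantifying longitudinal **lung shrinkage** on chest CT with deformable
registration and voxel-wise **log-Jacobian** maps.

In progressive fibrosing lung disease (idiopathic pulmonary fibrosis in
particular), parenchymal fibrosis pulls the lung inward over time, most
markedly at the bases. Side-by-side visual comparison of serial HRCT scans
is subjective; this package makes the change quantitative. A follow-up scan
is deformably aligned to its baseline, giving a dense displacement field
u(x) with T(x) = x + u(x). The Jacobian determinant of that transform,

    J(x) = det(I + ∂u/∂x),

is the local volume-change ratio at every voxel, and its natural logarithm
(log-Jacobian) is the per-voxel readout: **0 = unchanged, < 0 = shrinkage,
> 0 = expansion**. Per-patient masked means, craniocaudal regional means,
common-space group-mean maps, vessel volume/branch metrics, and
nonparametric cohort statistics (Mann-Whitney, Fisher exact, Spearman with
banded interpretation; functional deterioration defined as a ≥ 10
percentage-point FVC% or ≥ 15 percentage-point DLco% decline) complete the
analysis.

Everything is validated on synthetic longitudinal phantoms whose warps are
known **analytically** — so ground-truth log-Jacobian maps are exact, and
the whole pipeline is testable without any patient data.

It is intended for image-analysis researchers working on longitudinal CT
quantification: the library is the interface, with a thin `lungshrink` CLI
over it.

## Worked example

```python
import numpy as np
from lungshrink import (PhantomSpec, generate_phantom, register_deformable,
                        logjac_of_field, mean_logjac)

# synthetic baseline/follow-up pair: uniform 6% linear contraction (s = 0.94)
spec = PhantomSpec(grid_shape=(64, 64, 64), shrink_amplitude=0.06,
                   noise_sd=8.0, seed=1, scenario="deteriorate")
baseline, followup, lung_mask, truth = generate_phantom(spec)

field = register_deformable(baseline, followup, lung_mask.data)
jac = logjac_of_field(field)

print(f"truth mean log-Jacobian:     {truth.logjac_true.data[lung_mask.data].mean():.4f}")
print(f"recovered mean log-Jacobian: {mean_logjac(jac, lung_mask.data):.4f}")
print(f"expected 3 ln 0.94:          {3*np.log(0.94):.4f}")
```

prints

```
truth mean log-Jacobian:     -0.1856
recovered mean log-Jacobian: -0.1851
expected 3 ln 0.94:          -0.1856
```

i.e. registration recovers the built-in 6% contraction (3 ln 0.94 ≈ −0.186
of log-volume per voxel) to within 0.0005. A negative mean log-Jacobian
means the lung lost volume between visits.

The same flow end-to-end, from the shell:

```bash
lungshrink demo --out demo_out --seed 4 --grid 40
```

generates an eight-patient, three-group phantom cohort (worsening / stable
/ improving), runs preprocessing → field import → Jacobian analysis →
group maps → statistics, and prints each patient's mean log-Jacobian —
negative for the worsening group, 0 for stable, positive for improving —
alongside `cohort.csv`, group-mean map renders and a correlation report in
`demo_out/results/`.

Other subcommands (`phantom`, `preprocess`, `register`, `jacobian`,
`groupmap`, `vessels`, `stats`, `run`) expose the individual stages;
externally computed displacement fields (4-D NIfTI, mm, baseline grid) can
be supplied per patient in the cohort manifest instead of running the
built-in engine.

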