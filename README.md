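# oemri — oxygen-enhanced lung MRI analysis

`oemri` analyses two-gas-state inversion-recovery lung MRI of the kind used to
study emphysema in the mouse: magnitude images are acquired at several
inversion times while the animal breathes room air and again while it breathes
100% oxygen. From these the package quantifies, per pixel, three spatially
matched properties of the lung:

* **parenchymal density** — the fitted signal at full relaxation under air
  breathing, S0_air, proxies relative proton density;
* **oxygen uptake** — dissolved oxygen shortens T1, so
  ΔR1 = R1_O2 − R1_air (s⁻¹) tracks oxygen taken up into tissue and plasma;
* **oxygen delivery** — gaseous alveolar oxygen shortens T2*, recovered
  without a multi-echo experiment as ΔR2* = ln(S0_air / S0_O2) / TE (ms⁻¹).

The per-pixel signal model is the magnitude inversion-recovery curve
S(TI) = |S0 (1 − B e^(−R1·TI))| with inversion efficiency B (2 for a perfect
inversion), fitted independently per pixel by bounded nonlinear least squares.

On top of the maps the package implements the statistics used to compare a
saline-instilled control group against an elastase (PPE)-challenged group:
whole-lung ROI means and SDs with two-sample t-tests (global level vs
heterogeneity), equal-count binning of all pooled lung pixels by density or by
ΔR2* (20 bins of ~1,000 pixels), animal-level permutation tests of per-bin
group differences, and animal-resampling bootstrap SDs of the binned means.

Because raw data of such studies are rarely public, the package ships a
first-class synthetic-data module: digital lung phantoms whose group means,
within-animal SDs, between-animal spreads, density–uptake coupling and
uptake–delivery coupling reproduce the published group structure of the mouse
emphysema model, plus a forward simulator of the noisy image series. Every
analysis stage is therefore testable end-to-end, and recovery can be judged
against known ground truth.

Intended users: preclinical imaging scientists and methodologists who want a
tested reference implementation of the density/uptake/delivery analysis, or a
simulation bench for protocol and statistics choices.

## Worked example

```python
import numpy as np
from oemri import (AcquisitionProtocol, control_phantom_spec, make_phantom,
                   simulate_signal, fit_maps, summarize_roi)

protocol = AcquisitionProtocol()          # TIs 100..6000 ms, TE 0.5 ms
gt = make_phantom(control_phantom_spec(seed=1))
series = simulate_signal(gt, protocol, seed=2)
maps = fit_maps(series)

s = summarize_roi(maps)
print(f"valid pixels      {s.n_valid_pixels}")
print(f"S0_air   mean     {s.mean['s0_air']:.2f} a.u.")
print(f"R1_air   mean     {s.mean['r1_air']:.3f} 1/s")
print(f"dR1      mean     {s.mean['delta_r1']:.3f} 1/s")
print(f"dR2*     mean     {s.mean['delta_r2star']:.3f} 1/ms")
```

prints

```
valid pixels      851
S0_air   mean     3.42 a.u.
R1_air   mean     0.549 1/s
dR1      mean     0.026 1/s
dR2*     mean     0.078 1/ms
```

i.e. from ~850 noisy in-mask pixels that pass fit validation, the whole-lung
means recover the control-lung ground truth (density 3.29 a.u., R1 0.557 s⁻¹,
uptake 0.024 s⁻¹, delivery 0.071 ms⁻¹) to within the sampling noise of a
single simulated animal.

The same chain is available from the shell:

```bash
oemri simulate --seed 0 --out study/           # 9 control + 8 challenged
oemri fit      --input study/ --out fits/
oemri roi      --fits fits/ --out tables/
oemri bins     --fits fits/ --out tables/ --plot
oemri stats    --fits fits/ --out tables/
oemri run      --config pipeline.yaml          # all of the above
```

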