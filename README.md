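# spindlemech

Quantification toolkit for microneedle micromanipulation of the mammalian
mitotic spindle.

When a glass microneedle pulls laterally on a single kinetochore-fiber
(k-fiber) of a metaphase spindle, the way deformation spreads — and where
the fiber bends backwards — reports on how, where, and for how long the
spindle anchors its k-fibers.  `spindlemech` implements the full
quantification stack for such experiments:

- **Strain maps** between undeformed and deformed frames: structures are
  resampled to 100 equally spaced coordinates, rigid whole-spindle motion
  is removed by least-squares registration (Kabsch, reflection forbidden),
  and displacement magnitude *D* is summarized against distance *d* from
  the needle and fitted with *D = A·e^(−λd)* to give the spatial decay
  constant λ (µm⁻¹).
- **Signed curvature profiles** along traced fibers: κ(s) is the inverse
  radius of the circle through three points spanning a 1 µm window,
  positive at the needle bend and negative at the chromosome-proximal
  reverse bend; the global extrema are located and troughs below
  −0.1 µm⁻¹ are classified as chromosome- or pole-proximal.
- **Reinforcement lifetimes** from manipulate-and-hold series: the time
  for the chromosome-proximal negative curvature to disappear (sustained
  rise above the threshold), with censoring.
- **Spindle geometry metrics**: inter-kinetochore distance, pole-pole
  distance, plus-end-region angles to the pole-pole axis and between
  sisters, intensity-ratio profiles with half-max enrichment spans, and
  paired correlations.
- **Nonparametric statistics** (exact small-sample Mann-Whitney U and
  Wilcoxon signed-rank) and needle-position matching between conditions.
- **A synthetic spindle generator**: a discrete inextensible elastic rod
  for the manipulated fiber (bending stiffness B, anisotropic crosslink
  anchorage kc(s), hinged sprung pole, kinetochore tether), embedded in a
  bipolar scene with sister/neighbor fibers, needle ramp protocols, rigid
  jitter and smooth tracing noise — with full ground truth, so every
  analysis stage is testable end to end.  The crosslink profile realizes
  the two anchorage hypotheses: uniform along the fiber (model 1) versus
  chromosome-proximal enhancement over the first ~3 µm (model 2), whose
  turnover lifetime τ governs how long the reverse bend survives a hold.

See `docs/methods.md` for the model, its assumptions, parameter defaults
and limitations.

## Worked example

Simulate one wild-type 60 s manipulation (2.5 µm lateral pull) and
analyze it:

```python
from spindlemech import (RunConfig, SceneParams, Protocol,
                         generate_manipulation_series)
from spindlemech.pipeline import analyze_series

scene = SceneParams.wildtype(seed=42)
series, truth = generate_manipulation_series(scene, Protocol.pull60(u_needle=0.62))
res = analyze_series(series, RunConfig())

ex = res["extrema"]
print(f"kappa_max = {ex.kappa_max:+.2f} 1/um at s = {ex.s_max:.1f} um")
print(f"kappa_min = {ex.kappa_min:+.2f} 1/um at s = {ex.s_min:.1f} um "
      f"({res['classification']})")
print(f"decay constant = {res['decay_fit'].decay_constant:.2f} 1/um")
print(f"inter-KT change = {res['metric_changes']['interkt_um']:+.2f} um, "
      f"pole-pole change = {res['metric_changes']['pole_pole_um']:+.2f} um")
```

prints

```
kappa_max = +0.99 1/um at s = 4.8 um
kappa_min = -0.24 1/um at s = 1.9 um (chromosome_proximal)
decay constant = 0.43 1/um
inter-KT change = -0.04 um, pole-pole change = -1.39 um
```

The pulled fiber bends sharply at the needle (κ_max ≈ +1 µm⁻¹ at the
needle's arc position) and bends backwards ~2 µm from the chromosome
(κ_min ≈ −0.24 µm⁻¹): the chromosome-proximal reinforcement prevents the
fiber from pivoting at its plus-end.  Deformation decays away from the
needle with λ ≈ 0.4 µm⁻¹ (gone within ~5 µm), the inter-kinetochore
distance barely changes (sisters move as one unit), and the spindle
shortens.  Depleting the crosslinker (`SceneParams.prc1_rnai`) removes
the reverse bend and lets the inter-kinetochore distance grow instead.

A command-line interface wraps the same pipeline:

```sh
spindlemech simulate --out sim/ --seed 1 --protocol pull60 --n-cells 3
spindlemech analyze  --traces sim/traces.csv --out report/ --seed 1
spindlemech curvature --traces sim/traces.csv --out curv/ --seed 1
```

plus `strain`, `metrics`, and `reproduce-source-data` (which recomputes
decay fits and correlations from deposited source-data spreadsheets).

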