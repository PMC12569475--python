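# isoniche

Isotopic niche estimation and trophic competition metrics for sympatric
pelagic predators.

Large pelagic predators — swordfish (*Xiphias gladius*), blue shark
(*Prionace glauca*), shortfin mako (*Isurus oxyrinchus*) — share prey and
feeding grounds in the northeast Atlantic and western Mediterranean, and
coexist through trophic niche partitioning. `isoniche` quantifies that
partitioning from δ¹³C/δ¹⁵N stable isotope values, longline catch
records, and gridded environmental drivers:

- **Isotopic niches**: 2-D kernel utilization density (KUD) estimates of
  the (δ¹³C, δ¹⁵N) cloud per species and region or 1°×1° grid cell, their
  95% highest-density-region areas (‰², the niche width) and pairwise
  directional overlaps.
- **Interspecific competition**: the distance to competitors' centroids,
  CCD_i = (1/N) Σₖ ‖C_i − C_k‖₂ in isotope space — low CCD means similar
  resource use.
- **Intraspecific competition**: the intraspecific trophic pressure
  index, ITP = ln(nCPUE + 1)/KUD area — high for abundant species with
  narrow niches.
- **Abundance standardization**: negative-binomial additive models of
  longline catches (hooks offset, tensor-product spatial smooth, gear
  fixed factor, year/month/boat as penalized factors) predicting
  individuals per 1000 hooks (nCPUE) per grid cell.
- **Driver models**: gamma additive models relating CCD and ITP to
  productivity, mixed-layer depth, fishing effort and competitor
  abundance, with Spearman collinearity screening and AIC/deviance
  explained model selection.
- **Diet reconstruction**: a Bayesian stable isotope mixing model
  estimating diet proportions over prey source groups with
  diet-tissue discrimination factors, Dirichlet prior, Gelman–Rubin and
  Geweke convergence checks, and mixing-polygon validation.
- **Synthetic data**: generators reproducing the statistical structure of
  the study (per species × region bivariate-normal isotope clouds at the
  published moments, negative-binomial longline surveys, smooth driver
  fields, known-diet mixture consumers), so every stage is testable
  without any external download.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Estimate Mediterranean niches and competition indices on synthetic data
drawn at the published per-species moments:

```python
from isoniche.synthetic import gen_isotope_samples
from isoniche.niche import estimate_kud, kud_overlap
from isoniche.competition import compute_ccd, compute_centroids, compute_itp

samples = gen_isotope_samples(seed=1)          # defaults: the study's 9 groups
med = samples[samples.region == "w_mediterranean"]

niches = {}
for sp, grp in med.groupby("species"):
    try:
        niches[sp] = estimate_kud(grp[["d13c", "d15n"]].to_numpy(), species=sp)
    except Exception as e:
        print(f"{sp:>14}: skipped ({e})")
for sp, est in niches.items():
    print(f"{sp:>14}: n={est.n:3d}  KUD area={est.area:6.2f} per-mil^2  "
          f"centroid=({est.centroid[0]:.2f}, {est.centroid[1]:.2f})")

ov = kud_overlap(niches["swordfish"], niches["blue_shark"])
print(f"overlap: {ov.pct_a_in_b:.0f}% of the swordfish niche lies inside "
      f"the blue shark niche ({ov.pct_b_in_a:.0f}% the other way)")

ccd = compute_ccd(compute_centroids(samples, by="region"))
print(ccd[ccd.key == "w_mediterranean"].to_string(index=False))

itp = compute_itp(ncpue=2.5, kud_area=niches["swordfish"].area)
print(f"swordfish ITP at 2.5 ind/1000 hooks: {itp:.3f}")
```

Output:

```
 shortfin_mako: skipped (n=2 below minimum 10 for a KUD estimate)
    blue_shark: n= 45  KUD area= 21.95 per-mil^2  centroid=(-17.32, 11.12)
     swordfish: n=160  KUD area= 11.41 per-mil^2  centroid=(-18.26, 11.46)
overlap: 88% of the swordfish niche lies inside the blue shark niche (46% the other way)
            key       species      ccd  n_competitors
w_mediterranean    blue_shark 1.782367              2
w_mediterranean shortfin_mako 2.541473              2
w_mediterranean     swordfish 1.753413              2
swordfish ITP at 2.5 ind/1000 hooks: 0.110
```

Reading this: the blue shark occupies a niche roughly twice as wide as
the swordfish's (21.9 vs 11.4 ‰² — a generalist vs a narrower forager);
the swordfish niche is almost entirely nested inside the blue shark's
(88%) while covering under half of it (46%), so the two species exploit
strongly overlapping resources; the shortfin mako group is refused
because two individuals cannot support a density estimate. The ITP value
scales abundance against niche width — at equal abundance, the narrower
swordfish niche concentrates more intraspecific pressure per unit of
isotope space.

The full pipeline (samples + longline sets + driver layers + prey sources
→ niches → CCD/ITP → group tests → nCPUE surfaces → driver models →
diets) runs from a YAML config:

```sh
isoniche run --config run.yaml
```

and there are `isoniche kud / metrics / cpue` subcommands for the
individual stages.

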