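# cytodiff

Modelling and measurement tools for diffusion-limited T-cell immunotherapy
in solid tumours.

Cytotoxic γδ T cells kill breast-cancer cells largely through a secreted
small molecule (IFN-γ).  In a monolayer every cancer cell sees the secreted
dose; in tissue the molecule must diffuse outward from each (scarce) T cell
while tumour cells take it up, so its concentration decays over a
characteristic *penetration distance* `L = √(D/λ)`.  This package
implements:

* **a closed-form kill-fraction model** — the steady concentration around a
  spherical T-cell source, `σ(r)/σ_T = (R_T/r)·e^{−(r−R_T)/L}`, volume-
  averaged over the interaction sphere `R³ = R_T³ + R_C³/ρ` that one T cell
  shares with its `1/ρ` tumour cells (ρ = T-cell : tumour-cell ratio):

      f_kill(ρ) = f_max · ⟨σ/σ_T⟩_{R_T ≤ r ≤ R(ρ)}

  plus bounded least-squares fitting of `(f_max, L)` to dose–response data,
  an exactly-identified two-point solver, and penetration-distance scaling
  from a reference compound;
* **xenograft bookkeeping** — tumour mass ↔ cell counts, exponential
  interpolation of tumour burden, and the effective T-cell : tumour-cell
  ratio reached by a tail-vein injection;
* **automated apoptosis quantification** for CC3 (cleaved caspase-3,
  DAB/haematoxylin) brightfield tiles — CIELAB conversion, 3-way k-means,
  PCA channel decorrelation, maximum-entropy (Kapur) threshold refinement
  of the brown class, morphological clean-up, and the apoptotic index
  `AI = 100·Br/(Area − W)`;
* **synthetic generators** for both data types with exact ground truth, so
  the entire chain is testable without any external data.

See `docs/methods.md` for the model derivation, algorithmic details, and
design rationale.

## Worked example

Simulate a triplicate dose–response experiment from known parameters
(`f_max = 0.9`, `L = 20 µm`, noise s.d. 0.02), then refit them:

```sh
$ cytodiff simulate dose-response --out demo/dr --seed 5
wrote 30 points to demo/dr/dose_response.csv
$ cytodiff fit --in demo/dr/dose_response.csv --out demo/fit
f_kill_max=0.8918 L=19.64 µm R²=0.9960 p(L)=3.494e-08 n=30
```

The fit recovers the generating parameters to ~1–2 % (`f_max` 0.892 vs 0.9,
`L` 19.6 µm vs 20 µm); `R²` is the usual coefficient of determination and
`p(L)` the two-sided t-test of `L̂/SE(L̂)`, i.e. whether the data identify a
finite penetration distance at all.  `demo/fit/` also contains the fitted
curve (`curve.csv`) and a `run_record.json` for exact reproduction.

Bookkeeping for the tail-vein scenario (0.285 g tumour in a 25 g mouse,
10⁶ tumour cells injected at week 0, 10⁸ T cells at week 2, assessed at
week 4):

```sh
$ cytodiff estimate --out demo/est
...
"tumor_cells_at_assessment_millions": 285,
"tumor_cells_at_T_injection_millions": 17,
"tail_vein_ratio": 0.0675...
```

So although 100 million T cells were injected, body-wide distribution
leaves an effective T-cell : tumour-cell ratio of only ≈ 0.07 in the
tumour — two orders of magnitude below the co-injection ratios.

Segment synthetic CC3 tiles and quantify apoptosis:

```sh
$ cytodiff simulate histology --out demo/tiles --n-images 3 --seed 1
$ cytodiff segment --in demo/tiles --out demo/seg --seed 0
{"n_images": 3, "mean_index_percent": 18.82, "seed": 0}
```

`demo/seg/` holds per-image class masks, green-contour overlays, a
`results.csv` (`image,br_count,w_count,area,index_percent`) and a JSON
summary.  On these generated tiles the mean index is within 0.02
percentage points of the ground-truth brown fraction of tissue.

The same operations are available as a library:

```python
from cytodiff import KillModelParams, kill_fraction, fit_kill_model
from cytodiff.synthetic import gen_histology, SyntheticHistologySpec
from cytodiff.segmentation import quantify_image

params = KillModelParams(f_kill_max=0.9, L=20.0, d_T=3.0, d_C=7.0)
kill_fraction(15.0, params)          # predicted kill at rho = 15

img, truth = gen_histology(SyntheticHistologySpec(seed=0))
result, masks = quantify_image(img)  # result.index in percent
```

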