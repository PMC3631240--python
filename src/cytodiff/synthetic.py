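"""Synthetic inputs with the statistical structure the pipelines assume.

Two generators:

* :func:`gen_dose_response` — kill-fraction curves sampled from the
  closed-form model with additive Gaussian measurement noise, emulating the
  co-culture / xenograft dose–response experiments (default design: 10
  T-cell : tumour-cell ratios spanning the diffusion-limited regime, three
  replicates each, noise s.d. 0.02).

* :func:`gen_histology` — CC3-like brightfield tiles: near-achromatic
  background, elliptical haematoxylin-blue nuclei and DAB-brown apoptotic
  blobs, synthesised in CIELAB and converted to sRGB, with exact ground-truth
  class masks.  Class lightness means default to 105/120/124 (blue/white/
  brown on the 8-bit lightness scale) and the blue-vs-brown b* separation to
  10 — the regime in which blue and brown shades overlap enough that one-shot
  k-means leaves the brown class contaminated, which is exactly what the
  entropy-threshold refinement stage exists to fix.  Nucleus colour is drawn
  from a two-mode hue distribution (pure blue vs. partially DAB-stained
  brownish blue) to emulate staining variability.

Also exposes :func:`published_fixtures`: the published dose–response points and
apoptotic-index table as immutable in-memory datasets.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
from skimage import color, draw

from .bookkeeping import XenograftScenario, round_to_millions, tail_vein_ratio
from .errors import DomainError, PlacementError
from .kill_model import DoseResponsePoint, KillModelParams, kill_fraction
from .segmentation import ClassMasks

__all__ = [
    "SyntheticDoseResponseSpec",
    "SyntheticHistologySpec",
    "gen_dose_response",
    "gen_histology",
    "published_fixtures",
]

_DEFAULT_RHO = tuple(np.geomspace(0.005, 30.0, 10).tolist())


@dataclass(frozen=True)
class SyntheticDoseResponseSpec:
    """Design of a synthetic dose–response experiment."""

    params: KillModelParams = KillModelParams(0.9, 20.0)
    rho_values: tuple[float, ...] = _DEFAULT_RHO
    noise_sd: float = 0.02
    n_replicates: int = 3
    seed: int = 0
    convention: str = "shell"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        if any(r <= 0 for r in self.rho_values):
            raise DomainError("all rho values must be > 0")


def gen_dose_response(spec: SyntheticDoseResponseSpec) -> list[DoseResponsePoint]:
    """Model curve plus additive Gaussian noise, clipped to [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    rho = np.repeat(np.asarray(spec.rho_values, float), spec.n_replicates)
    f = kill_fraction(rho, spec.params, spec.convention)
    f = np.atleast_1d(f)
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, f.size)
    f = np.clip(f, 0.0, 1.0)
    return [
        DoseResponsePoint(float(r), float(fk), "synthetic") for r, fk in zip(rho, f)
    ]


@dataclass(frozen=True)
class SyntheticHistologySpec:
    """Geometry and colour statistics of a synthetic CC3-like tile.

    Lightness means are given on the 8-bit scale (L* × 255/100) for the
    blue / white / brown classes.  Chroma offsets are CIELAB (a*, b*) pairs;
    the default blue-vs-brown b* separation is 10.  Blue nuclei are drawn
    from two per-nucleus hue modes — pure blue, and partially DAB-stained
    "brownish blue" displaced by ``hue_shift`` toward the brown chroma — with
    the class mean chroma preserved; this is the shade variability that makes
    one-shot clustering merge part of the blue class into the brown one.
    ``noise_sd`` is i.i.d. Gaussian pixel noise, in 8-bit lightness units,
    applied to all three Lab channels (divided by 2.55).
    """

    height: int = 256
    width: int = 256
    n_blue_nuclei: int = 110
    n_brown_cells: int = 14
    blue_radius_range: tuple[float, float] = (4.0, 8.0)
    brown_radius_range: tuple[float, float] = (6.0, 10.0)
    L_means: tuple[float, float, float] = (105.0, 120.0, 124.0)  # blue, white, brown
    blue_chroma: tuple[float, float] = (10.0, -6.0)
    brown_chroma: tuple[float, float] = (11.0, 4.0)
    #: fraction of nuclei carrying partial DAB uptake ("brownish-blue" shade)
    brownish_fraction: float = 0.45
    #: chroma displacement (Δa*, Δb*) of brownish nuclei toward the brown hue;
    #: pure-blue nuclei are displaced opposite so the class mean chroma is kept
    hue_shift: tuple[float, float] = (1.0, 4.5)
    #: per-nucleus / per-blob lightness jitter (L* units)
    shade_sd: float = 1.5
    noise_sd: float = 3.0
    seed: int = 0
    max_place_tries: int = 200

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise DomainError("image dimensions must be positive")
        if self.noise_sd < 0 or self.shade_sd < 0:
            raise DomainError("noise and shade spreads must be non-negative")
        if not (0.0 <= self.brownish_fraction < 1.0):
            raise DomainError("brownish_fraction must lie in [0, 1)")


def _place_ellipses(rng, occupied, n, radius_range, max_tries):
    """Rejection-place n non-overlapping ellipses; returns list of index arrays."""
    H, W = occupied.shape
    shapes = []
    for _ in range(n):
        for attempt in range(max_tries):
            a = rng.uniform(*radius_range)
            b = rng.uniform(*radius_range)
            theta = rng.uniform(0, np.pi)
            r0 = rng.uniform(max(a, b), H - max(a, b))
            c0 = rng.uniform(max(a, b), W - max(a, b))
            rr, cc = draw.ellipse(r0, c0, a, b, shape=occupied.shape, rotation=theta)
            if rr.size == 0:
                continue
            if not occupied[rr, cc].any():
                occupied[rr, cc] = True
                shapes.append((rr, cc))
                break
        else:
            raise PlacementError(
                f"could not place ellipse {len(shapes) + 1}/{n} after {max_tries} tries"
            )
    return shapes


def gen_histology(
    spec: SyntheticHistologySpec,
) -> tuple[np.ndarray, ClassMasks]:
    """Generate one synthetic CC3-like tile and its ground-truth masks.

    Colours are synthesised in CIELAB (class means per the spec, two
    per-nucleus hue modes for blue, small per-shape lightness jitter), pixel
    noise added in Lab, then converted to 8-bit sRGB.  The returned masks
    partition the image exactly.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    L_blue, L_white, L_brown = (v / 2.55 for v in spec.L_means)

    lab = np.empty((H, W, 3), dtype=np.float64)
    lab[..., 0] = L_white
    lab[..., 1] = 0.0
    lab[..., 2] = 0.0

    occupied = np.zeros((H, W), dtype=bool)
    blue_shapes = _place_ellipses(
        rng, occupied, spec.n_blue_nuclei, spec.blue_radius_range, spec.max_place_tries
    )
    brown_shapes = _place_ellipses(
        rng, occupied, spec.n_brown_cells, spec.brown_radius_range, spec.max_place_tries
    )

    blue_mask = np.zeros((H, W), dtype=bool)
    brown_mask = np.zeros((H, W), dtype=bool)
    p = spec.brownish_fraction
    shift = np.asarray(spec.hue_shift, float)
    # opposite displacement of the pure-blue mode keeps the class mean chroma
    pure_shift = -shift * (p / (1.0 - p)) if p > 0 else np.zeros(2)
    for rr, cc in blue_shapes:
        brownish = rng.random() < p
        chroma = np.asarray(spec.blue_chroma, float) + (shift if brownish else pure_shift)
        lab[rr, cc, 0] = L_blue + rng.normal(0.0, spec.shade_sd)
        lab[rr, cc, 1] = chroma[0]
        lab[rr, cc, 2] = chroma[1]
        blue_mask[rr, cc] = True
    for rr, cc in brown_shapes:
        lab[rr, cc, 0] = L_brown + rng.normal(0.0, spec.shade_sd)
        lab[rr, cc, 1] = spec.brown_chroma[0]
        lab[rr, cc, 2] = spec.brown_chroma[1]
        brown_mask[rr, cc] = True

    if spec.noise_sd > 0:
        lab += rng.normal(0.0, spec.noise_sd / 2.55, lab.shape)
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)

    rgb = color.lab2rgb(lab)
    img = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    truth = ClassMasks(
        white=~(blue_mask | brown_mask), blue=blue_mask, brown=brown_mask
    )
    return img, truth


def published_fixtures() -> MappingProxyType:
    """The published datasets as immutable in-memory fixtures.

    ``in_vivo_points``: the three xenograft dose–response observations —
    co-injection at ρ = 15 (tumour burden 51.6 % of control → kill fraction
    0.484) and ρ = 30 (33.09 % → 0.6691), and the tail-vein experiment
    (ρ ≈ 0.0671 reconstructed from the mass-fraction argument, 22.1 %
    inhibition → 0.221).  ``in_vivo_no_outlier`` drops the ρ = 30 point,
    which the scarce-T-cell model explicitly does not cover.

    ``apoptosis_table``: apoptotic-index percentages of three images per
    imaging condition.
    """
    scenario = XenograftScenario(
        injected_tumor_cells=1e6,
        injected_T_cells=100e6,
        tumor_mass_g=0.285,
        body_mass_g=25.0,
        t_injection_weeks=2.0,
        t_assess_weeks=4.0,
    )
    # the published chain quotes the rounded "ca. 17 million" burden
    rho_tail = tail_vein_ratio(scenario, round_to_millions(
        1e6 * math.sqrt(285.0)) * 1e6)
    tail = DoseResponsePoint(rho_tail, 0.221, "tail-vein injection")
    co15 = DoseResponsePoint(15.0, 0.484, "co-injection 1:15")
    co30 = DoseResponsePoint(30.0, 0.6691, "co-injection 1:30")
    return MappingProxyType(
        {
            "in_vivo_points": (tail, co15, co30),
            "in_vivo_no_outlier": (tail, co15),
            "tail_vein_scenario": scenario,
            "apoptosis_table": MappingProxyType(
                {
                    "SKBR Only": (0.84, 1.41, 1.79),
                    "SKBR+1:15 T": (2.26, 4.67, 2.50),
                    "SKBR+1:30 T": (2.18, 1.84, 1.68),
                }
            ),
        }
    )
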