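"""CSV/JSON/PNG plumbing shared by the CLI and the tests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .kill_model import DoseResponsePoint, FitResult
from .segmentation import ApoptosisResult, ClassMasks

__all__ = [
    "read_dose_response",
    "write_dose_response",
    "write_curve",
    "write_fit",
    "write_results_csv",
    "masks_to_rgb",
    "overlay_contours",
]

#: mask-rendering palette (sRGB): background, nuclei, apoptotic regions
_PALETTE = {"white": (255, 255, 255), "blue": (60, 70, 180), "brown": (150, 90, 30)}


def read_dose_response(path, percent: bool = False) -> list[DoseResponsePoint]:
    """Read a ``rho,f_kill[,label]`` CSV into dose-response points.

    ``percent=True`` divides the kill column by 100.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # parse errors surface as FormatError
        raise FormatError(f"could not parse {path}: {exc}") from exc
    required = {"rho", "f_kill"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path} must have columns rho,f_kill[,label]; found {list(df.columns)}"
        )
    scale = 0.01 if percent else 1.0
    labels = df["label"] if "label" in df.columns else [""] * len(df)
    try:
        return [
            DoseResponsePoint(float(r), float(f) * scale, str(lab))
            for r, f, lab in zip(df["rho"], df["f_kill"], labels)
        ]
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric dose-response values in {path}: {exc}") from exc


def write_dose_response(points: Sequence[DoseResponsePoint], path) -> None:
    pd.DataFrame(
        {
            "rho": [p.rho for p in points],
            "f_kill": [p.f_kill for p in points],
            "label": [p.label for p in points],
        }
    ).to_csv(path, index=False)


def write_curve(rho: Iterable[float], f_pred: Iterable[float], path) -> None:
    pd.DataFrame({"rho": list(rho), "f_kill_pred": list(f_pred)}).to_csv(
        path, index=False
    )


def write_fit(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result.as_dict(), indent=2) + "\n")


def write_results_csv(results: Sequence[ApoptosisResult], path) -> None:
    pd.DataFrame(
        {
            "image": [r.image_id for r in results],
            "br_count": [r.br_count for r in results],
            "w_count": [r.w_count for r in results],
            "area": [r.area for r in results],
            "index_percent": [r.index for r in results],
        }
    ).to_csv(path, index=False)


def masks_to_rgb(masks: ClassMasks) -> np.ndarray:
    """Render class masks as an 8-bit RGB image with the standard palette."""
    out = np.zeros(masks.shape + (3,), dtype=np.uint8)
    for name, rgb in _PALETTE.items():
        out[getattr(masks, name)] = rgb
    return out


def overlay_contours(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Draw a green contour of ``mask`` onto a copy of ``img``."""
    from skimage.segmentation import find_boundaries

    out = np.asarray(img).copy()
    edge = find_boundaries(np.asarray(mask, bool), mode="outer")
    out[edge] = (0, 220, 0)
    return out
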