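"""Compartmentalized immunofluorescence quantification.

Measures total, plasma-membrane and perinuclear signal in single-plane
16-bit cell images with a compartment label mask, subtracting the mean
background intensity measured adjacent to the cell, and quantifies
within-compartment signal heterogeneity. Masks are inputs (drawn or
generated), mirroring a manual region-of-interest workflow; automatic
segmentation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .core import CompartmentImage

__all__ = [
    "CompartmentSignal",
    "measure_compartments",
    "signal_variability",
    "write_compartment_image",
    "read_compartment_image",
    "QUANTIFIED_COMPARTMENTS",
]

QUANTIFIED_COMPARTMENTS = ("total", "membrane", "perinuclear")

# alternatives to pixel CV for the variability metric
_VARIABILITY_METRICS = ("cv", "sd", "iqr_over_median")


@dataclass
class CompartmentSignal:
    """Background-corrected intensity summary of one compartment.

    ``mean_corrected = mean_raw − background_mean``, floored at zero
    with ``floored=True`` when the subtraction goes negative.
    ``variability`` is the coefficient of variation of the corrected
    pixel intensities within the compartment (population sd / mean).
    """

    compartment: str
    mean_raw: float = float("nan")
    background_mean: float = float("nan")
    mean_corrected: float = float("nan")
    variability: float = float("nan")
    n_pixels: int = 0
    floored: bool = False
    missing: dict = field(default_factory=dict)


def _background_mean(image: CompartmentImage) -> float:
    bg = image.compartment_mask("background")
    if not bg.any():
        raise ValueError("background mask is empty")
    return float(image.pixels[bg].mean())


def measure_compartments(image: CompartmentImage) -> list:
    """Quantify each compartment: raw mean, background mean, corrected mean, CV.

    Compartments are ``total`` (union of all cell labels), ``membrane``
    and ``perinuclear``. An empty compartment mask yields a missing
    entry rather than an error; a corrected mean below zero is floored
    and flagged.
    """
    bg_mean = _background_mean(image)
    out = []
    for name in QUANTIFIED_COMPARTMENTS:
        sig = CompartmentSignal(compartment=name, background_mean=bg_mean)
        mask = image.compartment_mask(name)
        sig.n_pixels = int(mask.sum())
        if sig.n_pixels == 0:
            sig.missing["all"] = f"compartment {name!r} mask is empty"
            out.append(sig)
            continue
        px = image.pixels[mask]
        sig.mean_raw = float(px.mean())
        corrected = sig.mean_raw - bg_mean
        if corrected < 0:
            sig.mean_corrected = 0.0
            sig.floored = True
        else:
            sig.mean_corrected = corrected
        try:
            sig.variability = signal_variability(image, name)
        except ValueError as exc:
            sig.missing["variability"] = str(exc)
        out.append(sig)
    return out


def signal_variability(image: CompartmentImage, compartment: str,
                       metric: str = "cv") -> float:
    """Heterogeneity of background-subtracted pixel intensities in a compartment.

    Default metric is the coefficient of variation (population sd over
    mean); ``sd`` and ``iqr_over_median`` are available alternatives.
    Both CV and IQR/median are invariant to positive rescaling of the
    corrected image. Requires ≥ 10 pixels and a positive corrected
    mean.
    """
    if metric not in _VARIABILITY_METRICS:
        raise ValueError(f"metric must be one of {_VARIABILITY_METRICS}")
    mask = image.compartment_mask(compartment)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"compartment {compartment!r} has {n} pixels; need at least 10")
    corrected = image.pixels[mask] - _background_mean(image)
    mean = corrected.mean()
    if metric == "sd":
        return float(corrected.std())
    if mean <= 0:
        raise ValueError(
            f"corrected mean of {compartment!r} is non-positive ({mean:.3g}); "
            "variability undefined")
    if metric == "iqr_over_median":
        q1, med, q3 = np.percentile(corrected, [25, 50, 75])
        return float((q3 - q1) / med)
    return float(corrected.std() / mean)


def write_compartment_image(image: CompartmentImage, path) -> None:
    """Write pixels as 16-bit single-plane TIFF and masks as an 8-bit label TIFF.

    The label file sits next to the image as ``<stem>_mask.tif`` with
    codes 0=background, 1=cytoplasm, 2=membrane, 3=perinuclear.
    """
    path = Path(path)
    pixels = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pixels)
    tifffile.imwrite(path.with_name(path.stem + "_mask.tif"),
                     image.masks.astype(np.uint8))


def read_compartment_image(path, mask_path=None,
                           pixel_size: Optional[float] = None) -> CompartmentImage:
    """Read an image TIFF plus its label-mask TIFF into a CompartmentImage."""
    path = Path(path)
    if mask_path is None:
        mask_path = path.with_name(path.stem + "_mask.tif")
    mask_path = Path(mask_path)
    if not mask_path.exists():
        raise FileNotFoundError(f"label mask not found: {mask_path}")
    pixels = tifffile.imread(path)
    masks = tifffile.imread(mask_path)
    return CompartmentImage(pixels=np.asarray(pixels, dtype=float),
                            masks=np.asarray(masks), pixel_size=pixel_size)
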