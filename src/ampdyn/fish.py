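"""FISH biovolume quantification from paired probe/DAPI binary masks.

A field of view (FOV) contributes one ratio: probe-positive pixels over
DAPI-positive pixels.  The per-sample biovolume fraction is the mean of the
per-FOV ratios (FOVs with an empty DAPI mask are excluded and counted), a
sequencing-independent estimate of the share of biomass a probe-targeted
population occupies.  Segmentation of raw micrographs is upstream; this
module consumes binary masks only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass
class FOVPair:
    probe_mask: np.ndarray
    dapi_mask: np.ndarray

    def __post_init__(self) -> None:
        self.probe_mask = np.asarray(self.probe_mask).astype(bool)
        self.dapi_mask = np.asarray(self.dapi_mask).astype(bool)
        if self.probe_mask.shape != self.dapi_mask.shape:
            raise ValueError(
                f"mask dimensions differ: {self.probe_mask.shape} vs {self.dapi_mask.shape}"
            )


@dataclass
class BiovolumeEstimate:
    ratios: np.ndarray  # per usable FOV
    mean: float
    sem: float
    n_fov: int
    n_excluded: int


def biovolume_fov(fov: FOVPair, intersect: bool = False) -> float | None:
    """Probe/DAPI positive-pixel ratio for one FOV; None signals an excluded
    FOV (no DAPI signal).  ``intersect`` restricts probe pixels to those
    inside the DAPI mask."""
    n_dapi = int(fov.dapi_mask.sum())
    if n_dapi == 0:
        return None
    probe = fov.probe_mask & fov.dapi_mask if intersect else fov.probe_mask
    return float(probe.sum() / n_dapi)


def biovolume_sample(
    fovs: list[FOVPair], intersect: bool = False, pooled: bool = False
) -> BiovolumeEstimate:
    """Biovolume fraction for one sample from its FOVs.

    Default: mean and SEM of the per-FOV ratios.  ``pooled`` instead divides
    total probe pixels by total DAPI pixels (exposed as an option; per-FOV
    averaging is the primary mode)."""
    ratios = []
    n_excluded = 0
    for fov in fovs:
        r = biovolume_fov(fov, intersect=intersect)
        if r is None:
            n_excluded += 1
        else:
            ratios.append(r)
    if not ratios:
        raise ValueError("no usable FOVs (all DAPI masks empty)")
    arr = np.asarray(ratios)
    if pooled:
        dapi_tot = sum(int(f.dapi_mask.sum()) for f in fovs)
        probe_tot = sum(
            int((f.probe_mask & f.dapi_mask if intersect else f.probe_mask).sum())
            for f in fovs
        )
        mean = probe_tot / dapi_tot
    else:
        mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return BiovolumeEstimate(arr, float(mean), sem, len(arr), n_excluded)


def correlate_fish_amplicon(
    biovolumes: np.ndarray, rel_abund: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (and two-tailed p via the t transform) between a
    per-time-point FISH biovolume series and an amplicon relative-abundance
    series for the same taxon."""
    x = np.asarray(biovolumes, dtype=float)
    y = np.asarray(rel_abund, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be aligned on the same time points")
    if len(x) < 3:
        raise ValueError("need >= 3 time points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


_FOV_PATTERN = re.compile(r"^(?P<sample>.+)_(?P<fov>[^_]+)_(?P<kind>probe|dapi)\.\w+$")


def load_fov_directory(path: str | Path) -> dict[str, list[FOVPair]]:
    """Load paired masks named ``<sample>_<fov>_{probe|dapi}.<ext>`` (PNG or
    PGM; any nonzero pixel is positive) into per-sample FOV lists."""
    import imageio.v3 as iio

    pairs: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for file in sorted(Path(path).iterdir()):
        m = _FOV_PATTERN.match(file.name)
        if not m:
            continue
        key = (m["sample"], m["fov"])
        pairs.setdefault(key, {})[m["kind"]] = np.asarray(iio.imread(file)) > 0
    out: dict[str, list[FOVPair]] = {}
    for (sample, fov), masks in sorted(pairs.items()):
        if "probe" not in masks or "dapi" not in masks:
            raise ValueError(f"FOV {sample}_{fov} is missing its probe or dapi mask")
        out.setdefault(sample, []).append(FOVPair(masks["probe"], masks["dapi"]))
    return out


def save_fov_directory(
    fovs_by_sample: dict[str, list[FOVPair]], path: str | Path
) -> None:
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for sample, fovs in fovs_by_sample.items():
        for i, fov in enumerate(fovs, start=1):
            iio.imwrite(
                path / f"{sample}_{i:03d}_probe.png",
                (fov.probe_mask.astype(np.uint8) * 255),
            )
            iio.imwrite(
                path / f"{sample}_{i:03d}_dapi.png",
                (fov.dapi_mask.astype(np.uint8) * 255),
            )
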