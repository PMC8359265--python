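"""Substantia nigra measurements from neuromelanin-sensitive MRI.

The neuromelanin–iron complex of SN pars compacta neurons is paramagnetic
and appears hyperintense on T1 turbo-spin-echo images of the midbrain.
Four per-subject measurements are derived from a manually (or synthetically)
delineated SN region of interest and a background ROI covering the tegmentum:

``Vol``
    SN volume: voxel count of the SN ROI on the 3 lowest contiguous slices
    in which the SN is visible, times the voxel volume (mm^3).
``C_vol``
    Vol normalised by total intracranial volume (mm^3 / cm^3); removes the
    head-size contribution and, with it, most scanner offsets.
``SNR``
    mean over slices of (mean SN signal / mean background signal) x 100.
    100 means no contrast.
``CNR``
    mean over slices of (mean SN signal - mean background signal) / SD of
    background signal.

Percent differences and annualized rates use the same conventions as the
group analyses: ratio-referenced for Vol, C_vol and CNR, and referenced to
(SNR - 100) for SNR, since the raw SNR ratio buries the contrast in the
100-point background pedestal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical measurement names, in reporting order
MEASURES = ("vol", "cvol", "snr", "cnr")

#: SNR of a zero-contrast region (ratio of equal means, x100)
SNR_BACKGROUND_REFERENCE = 100.0

_KIND_ALIASES = {
    "vol": "vol",
    "volume": "vol",
    "cvol": "cvol",
    "c_vol": "cvol",
    "snr": "snr",
    "cnr": "cnr",
}


def _canonical_kind(measure_kind: str) -> str:
    try:
        return _KIND_ALIASES[measure_kind.lower()]
    except KeyError:
        raise ValueError(
            f"unknown measure kind {measure_kind!r}; expected one of {sorted(set(_KIND_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class NMImageVolume:
    """A 3-D neuromelanin-sensitive image.

    The slice (third) axis runs inferior -> superior: slice index 0 is the
    most caudal slice. ``voxel_size`` is (dx, dy, dz) in mm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 3.0)
    orientation: str = "inferior-to-superior"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"image must be 3-D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("image contains non-finite intensities")
        if len(self.voxel_size) != 3 or any(d <= 0 for d in self.voxel_size):
            raise ValueError(f"voxel dimensions must be positive, got {self.voxel_size}")
        if self.orientation != "inferior-to-superior":
            raise ValueError(
                "only the 'inferior-to-superior' slice-axis convention is supported; "
                "reorient the image before constructing NMImageVolume"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", tuple(float(d) for d in self.voxel_size))

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass(frozen=True)
class ROIMaskPair:
    """SN mask and background mask on the same grid as the image.

    Masks must be disjoint, and the background mask must be nonempty on
    every slice where the SN mask is nonempty (SNR/CNR are per-slice
    ratios against the background).
    """

    sn_mask: np.ndarray
    bnd_mask: np.ndarray

    def __post_init__(self) -> None:
        sn = np.asarray(self.sn_mask, dtype=bool)
        bnd = np.asarray(self.bnd_mask, dtype=bool)
        if sn.ndim != 3 or bnd.ndim != 3:
            raise ValueError("masks must be 3-D")
        if sn.shape != bnd.shape:
            raise ValueError(f"mask shapes differ: {sn.shape} vs {bnd.shape}")
        if np.any(sn & bnd):
            raise ValueError("SN and background masks overlap")
        sn_slices = np.flatnonzero(sn.any(axis=(0, 1)))
        bnd_per_slice = bnd.any(axis=(0, 1))
        missing = [int(k) for k in sn_slices if not bnd_per_slice[k]]
        if missing:
            raise ValueError(f"background mask empty on SN-bearing slices {missing}")
        object.__setattr__(self, "sn_mask", sn)
        object.__setattr__(self, "bnd_mask", bnd)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.sn_mask.shape


@dataclass(frozen=True)
class SliceSignalSummary:
    """Per-slice signal aggregates entering SNR/CNR."""

    slice_index: int
    sig_sn: float
    sig_bnd: float
    std_bnd: float
    n_sn_voxels: int


@dataclass(frozen=True)
class SNMeasurements:
    """The four per-subject-visit SN measurements."""

    vol_mm3: float
    tiv_cm3: float
    cvol: float
    snr: float
    cnr: float
    slices_used: tuple[int, int, int]


class SNNotMeasurableError(ValueError):
    """Raised when no run of 3 contiguous slices shows the SN."""


def select_measurement_slices(
    sn_mask: np.ndarray, min_voxels: int = 1
) -> tuple[int, int, int]:
    """Return the most inferior run of 3 contiguous slices with a visible SN.

    A slice counts as "visible" when it carries at least ``min_voxels`` SN
    voxels. Slice index 0 is the most inferior slice.
    """
    sn_mask = np.asarray(sn_mask, dtype=bool)
    counts = sn_mask.sum(axis=(0, 1))
    visible = counts >= min_voxels
    for k in range(len(visible) - 2):
        if visible[k] and visible[k + 1] and visible[k + 2]:
            return (k, k + 1, k + 2)
    # name the longest available run in the error, per the measurement contract
    best = run = 0
    for v in visible:
        run = run + 1 if v else 0
        best = max(best, run)
    raise SNNotMeasurableError(
        f"SN not measurable: need 3 contiguous slices with >= {min_voxels} voxels, "
        f"longest available run is {best}"
    )


def summarize_slices(
    image: NMImageVolume,
    masks: ROIMaskPair,
    slices: Sequence[int],
    ddof: int = 1,
) -> list[SliceSignalSummary]:
    """Per-slice SN/background means and background SD over the given slices.

    ``ddof=1`` (sample SD) is the default background-SD estimator; pass
    ``ddof=0`` for the population form.
    """
    if masks.shape != image.data.shape:
        raise ValueError("mask grid does not match image grid")
    out = []
    for k in slices:
        sn_vals = image.data[:, :, k][masks.sn_mask[:, :, k]]
        bnd_vals = image.data[:, :, k][masks.bnd_mask[:, :, k]]
        if sn_vals.size == 0:
            raise ValueError(f"SN mask empty on selected slice {k}")
        if bnd_vals.size == 0:
            raise ValueError(f"background mask empty on selected slice {k}")
        out.append(
            SliceSignalSummary(
                slice_index=int(k),
                sig_sn=float(sn_vals.mean()),
                sig_bnd=float(bnd_vals.mean()),
                std_bnd=float(bnd_vals.std(ddof=ddof)) if bnd_vals.size > ddof else 0.0,
                n_sn_voxels=int(sn_vals.size),
            )
        )
    return out


def compute_volume(
    sn_mask: np.ndarray,
    slices: Sequence[int],
    voxel_size: Sequence[float],
) -> float:
    """SN volume in mm^3: voxel count on ``slices`` times the voxel volume."""
    sn_mask = np.asarray(sn_mask, dtype=bool)
    dx, dy, dz = voxel_size
    count = int(sum(int(sn_mask[:, :, k].sum()) for k in slices))
    return count * dx * dy * dz


def compute_cvol(vol_mm3: float, tiv_cm3: float) -> float:
    """Head-size-corrected volume, Vol[mm^3] / TIV[cm^3]."""
    if tiv_cm3 <= 0:
        raise ValueError(f"TIV must be positive, got {tiv_cm3}")
    return vol_mm3 / tiv_cm3


def compute_snr(summaries: Iterable[SliceSignalSummary]) -> float:
    """Mean over slices of (Sig_SN / Sig_BND) x 100."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no slice summaries")
    for s in summaries:
        if s.sig_bnd <= 0:
            raise ValueError(f"nonpositive background signal on slice {s.slice_index}")
    return float(np.mean([s.sig_sn / s.sig_bnd * 100.0 for s in summaries]))


def compute_cnr(summaries: Iterable[SliceSignalSummary]) -> float:
    """Mean over slices of (Sig_SN - Sig_BND) / STD_BND."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no slice summaries")
    for s in summaries:
        if s.std_bnd <= 0:
            raise ValueError(
                f"zero/negative background SD on slice {s.slice_index}; "
                "CNR undefined on a noiseless background"
            )
    return float(np.mean([(s.sig_sn - s.sig_bnd) / s.std_bnd for s in summaries]))


def measure(
    image: NMImageVolume,
    masks: ROIMaskPair,
    tiv_cm3: float,
    min_voxels: int = 1,
    ddof: int = 1,
) -> SNMeasurements:
    """Run the full per-scan measurement: slice selection, Vol, C_vol, SNR, CNR."""
    slices = select_measurement_slices(masks.sn_mask, min_voxels=min_voxels)
    summaries = summarize_slices(image, masks, slices, ddof=ddof)
    vol = compute_volume(masks.sn_mask, slices, image.voxel_size)
    return SNMeasurements(
        vol_mm3=vol,
        tiv_cm3=float(tiv_cm3),
        cvol=compute_cvol(vol, tiv_cm3),
        snr=compute_snr(summaries),
        cnr=compute_cnr(summaries),
        slices_used=slices,
    )


def percent_difference(value, reference, measure_kind: str):
    """Percent difference of ``value`` relative to ``reference``.

    Vol, C_vol, CNR: (value - reference) / reference x 100.
    SNR: (value - reference) / (reference - 100) x 100 — referenced to the
    contrast above the background pedestal, because an SNR of 100 carries no
    SN signal at all.
    Accepts scalars or arrays (broadcasting elementwise).
    """
    kind = _canonical_kind(measure_kind)
    value = np.asarray(value, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if kind == "snr":
        denom = reference - SNR_BACKGROUND_REFERENCE
        if np.any(denom == 0):
            raise ValueError("SNR reference equals the 100 background level; percent difference undefined")
    else:
        denom = reference
        if np.any(denom == 0):
            raise ValueError("zero reference value; percent difference undefined")
    out = (value - reference) / denom * 100.0
    return float(out) if out.ndim == 0 else out


def annual_rate(measure_v1, measure_v2, delay_years, measure_kind: str):
    """Annualized percent change: percent_difference(V2 vs V1) / delay (years)."""
    delay = np.asarray(delay_years, dtype=float)
    if np.any(delay <= 0):
        raise ValueError("inter-visit delay must be positive")
    out = percent_difference(measure_v2, measure_v1, measure_kind) / delay
    return float(out) if np.ndim(out) == 0 else out


def mean_annual_rates(
    table: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
    subject_col: str = "subject_id",
    visit_col: str = "visit",
    delay_col: str = "delay_years",
) -> tuple[dict[str, float], int]:
    """Cohort mean annualized rates from a long (one row per subject-visit) table.

    Per-subject rates are computed for subjects with both visits and then
    averaged (not a ratio of group means). Returns the per-measure means and
    the number of subjects excluded for a missing V2.
    """
    visits = set(table[visit_col].unique())
    if not visits <= {"V1", "V2"}:
        raise ValueError(f"unexpected visit labels {visits - {'V1', 'V2'}}")
    wide = table.pivot(index=subject_col, columns=visit_col, values=list(measures) + [delay_col])
    # delay is only defined at V2; require both visit values per measure plus the delay
    needed = [(m, v) for m in measures for v in ("V1", "V2")] + [(delay_col, "V2")]
    present = [c for c in needed if c in wide.columns]
    complete = wide.dropna(subset=present) if len(present) == len(needed) else wide.iloc[:0]
    n_excluded = len(wide) - len(complete)
    if n_excluded:
        logger.info("mean_annual_rates: excluded %d subjects missing a visit", n_excluded)
    if complete.empty:
        raise ValueError("no subjects with both visits")
    rates = {}
    delay = complete[(delay_col, "V2")].to_numpy()
    for m in measures:
        rates[m] = float(
            np.mean(
                annual_rate(
                    complete[(m, "V1")].to_numpy(),
                    complete[(m, "V2")].to_numpy(),
                    delay,
                    m,
                )
            )
        )
    return rates, n_excluded
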