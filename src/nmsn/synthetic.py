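"""Synthetic midbrain cohorts: phantom images, ROI masks and subject tables.

No raw imaging data accompanies the study design this package implements, so
every downstream stage is exercised on a generative stand-in with the same
statistical structure:

* **Phantoms** — a noisy tegmentum-like background at 0.4 x 0.4 x 3 mm^3
  voxels with two hyperintense ellipsoidal SN blobs of controlled volume and
  contrast, plus a disjoint rectangular background ROI dorsal to them.
* **Cohorts** — one row per subject per visit, with group deficits at
  baseline (early PD ~ -11% Vol, progressing ~ -38%), programmed annualized
  declines (-5.8 %/yr early, -10.2 %/yr progressing, healthy volunteers
  ~flat), sex and scanner offsets, and motor scores (MDS-UPDRS-III OFF)
  negatively correlated with C_vol by bivariate-normal construction.
* **Rater perturbations** — boundary-voxel toggling of a mask, emulating a
  second examiner for Dice/ICC reliability estimation.

All randomness flows from explicit integer seeds; equal seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .quantify import NMImageVolume, ROIMaskPair

__all__ = [
    "PhantomSpec",
    "CohortDesign",
    "RaterPerturbation",
    "generate_phantom",
    "generate_cohort",
    "perturb_mask",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of a single midbrain phantom.

    The grid is a scaled-down field of view (default 96 x 96 x 12) at the
    acquisition's native voxel size. ``sn_target_volume`` is the volume of
    ONE SN side in mm^3; both sides together make the per-subject Vol.
    ``sn_target_snr`` is on the x100 ratio scale (100 = no contrast).
    ``bnd_sd`` may be zero for a noiseless phantom (then CNR is undefined).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 12)
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 3.0)
    bnd_mean: float = 100.0
    bnd_sd: float = 7.7
    sn_target_volume: float = 136.6
    sn_target_snr: float = 112.0
    n_sn_slices: int = 3

    def __post_init__(self) -> None:
        if self.sn_target_snr <= 0:
            raise ValueError("sn_target_snr must be positive")
        if self.bnd_sd < 0:
            raise ValueError("bnd_sd must be nonnegative")
        if self.bnd_mean <= 0:
            raise ValueError("bnd_mean must be positive")
        if self.n_sn_slices < 3:
            raise ValueError("need at least 3 SN-bearing slices")
        if self.sn_target_volume <= 0:
            raise ValueError("sn_target_volume must be positive")
        if self.n_sn_slices > self.grid_shape[2]:
            raise ValueError("n_sn_slices exceeds grid depth")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


def _exact_count_ellipsoid(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    center_vox: tuple[float, float],
    z_run: tuple[int, int],
    n_voxels: int,
) -> np.ndarray:
    """Boolean ellipsoid with exactly ``n_voxels`` voxels.

    Voxels inside the z run are ranked by the ellipsoidal quadratic form
    q = (in-plane squared distance) / (1 - ((z - cz)/c)^2) and the
    ``n_voxels`` smallest are kept; the level set {q <= a^2} is exactly the
    ellipsoid with in-plane semi-axis a, so the result is an ellipsoid whose
    semi-axis is set by the requested count. Fractional center offsets break
    grid symmetry so the count is attainable exactly.
    """
    nx, ny, nz = shape
    dx, dy, dz = voxel_size
    z0, n_sl = z_run
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    cx, cy = center_vox[0] * dx, center_vox[1] * dy
    cz = (z0 + n_sl / 2.0) * dz
    c = n_sl / 2.0 * dz
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    mask = np.zeros(shape, dtype=bool)
    q_all, idx_all = [], []
    for k in range(z0, z0 + n_sl):
        zk = (k + 0.5) * dz
        rel = 1.0 - ((zk - cz) / c) ** 2
        q = r2 / rel
        q_all.append(q.ravel())
        idx_all.append(np.stack([*np.indices((nx, ny)).reshape(2, -1), np.full(nx * ny, k)]))
    q_flat = np.concatenate(q_all)
    idx_flat = np.concatenate(idx_all, axis=1)
    order = np.argpartition(q_flat, n_voxels)[:n_voxels]
    mask[idx_flat[0, order], idx_flat[1, order], idx_flat[2, order]] = True
    return mask


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[NMImageVolume, ROIMaskPair]:
    """Render one midbrain phantom and its SN/background ROI pair.

    The image is Gaussian background noise N(bnd_mean, bnd_sd^2) everywhere,
    with the two SN ellipsoids raised to mean ``bnd_mean x snr/100``. The SN
    mask spans exactly ``n_sn_slices`` contiguous slices centred in the
    grid; the background ROI is a fixed rectangle dorsal to the blobs on
    every slice, disjoint from the SN by construction.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    z0 = (nz - spec.n_sn_slices) // 2
    n_side = int(round(spec.sn_target_volume / spec.voxel_volume_mm3))
    if n_side < spec.n_sn_slices:
        raise ValueError("sn_target_volume too small for the requested slice count")

    # irrational-ish fractional offsets so the voxel ranking has no ties
    left = _exact_count_ellipsoid(
        spec.grid_shape, spec.voxel_size, (0.32 * nx + 0.137, 0.38 * ny + 0.071),
        (z0, spec.n_sn_slices), n_side,
    )
    right = _exact_count_ellipsoid(
        spec.grid_shape, spec.voxel_size, (0.68 * nx + 0.263, 0.38 * ny + 0.129),
        (z0, spec.n_sn_slices), n_side,
    )
    if np.any(left & right):
        raise ValueError("SN ellipsoids overlap: grid too small for sn_target_volume")
    sn = left | right
    occupied = np.flatnonzero(sn.any(axis=(0, 1)))
    if len(occupied) != spec.n_sn_slices:
        raise ValueError(
            f"SN spans {len(occupied)} slices instead of {spec.n_sn_slices}; "
            "increase sn_target_volume or reduce n_sn_slices"
        )
    # sanity: blobs must stay clear of the grid edge
    xs, ys, _ = np.nonzero(sn)
    if xs.min() == 0 or xs.max() == nx - 1 or ys.min() == 0 or ys.max() == ny - 1:
        raise ValueError("SN ellipsoid touches the grid boundary: grid too small")

    bnd = np.zeros(spec.grid_shape, dtype=bool)
    bnd[int(0.30 * nx): int(0.70 * nx), int(0.55 * ny): int(0.80 * ny), :] = True
    if np.any(bnd & sn):
        raise ValueError("background ROI overlaps the SN: grid geometry infeasible")

    rng = np.random.default_rng(seed)
    data = spec.bnd_mean + rng.normal(0.0, spec.bnd_sd, size=spec.grid_shape) if spec.bnd_sd > 0 \
        else np.full(spec.grid_shape, spec.bnd_mean, dtype=float)
    data = np.asarray(data, dtype=float)
    data[sn] += spec.bnd_mean * (spec.sn_target_snr - 100.0) / 100.0
    image = NMImageVolume(data=data, voxel_size=spec.voxel_size)
    return image, ROIMaskPair(sn_mask=sn, bnd_mask=bnd)


@dataclass(frozen=True)
class RaterPerturbation:
    """Boundary-toggling model of a second (or repeat) rater.

    ``in_plane=True`` (default) restricts the boundary to each slice's 2-D
    contour, matching how raters trace slice by slice: a second rater
    disagrees about the contour, not about which slices carry SN at all.
    """

    #: default calibrated so the expected Dice against the original mask
    #: falls in the 0.82-0.85 range reported for trained human raters
    boundary_shift_prob: float = 0.5
    seed: int = 0
    in_plane: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.boundary_shift_prob <= 1.0:
            raise ValueError("boundary_shift_prob must lie in [0, 1]")


def perturb_mask(mask: np.ndarray, perturbation: RaterPerturbation) -> np.ndarray:
    """Toggle boundary voxels of ``mask`` with probability ``boundary_shift_prob``.

    The boundary is the union of the inner shell (mask voxels with a
    non-mask neighbour) and the outer shell (non-mask voxels adjacent to
    the mask); interior voxels are never touched, so the expected Dice
    against the original decreases monotonically in the shift probability.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot perturb an empty mask")
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    if perturbation.in_plane and mask.ndim == 3:
        # neighbourhood confined to the slice plane (third axis = slices)
        structure = structure.copy()
        structure[1, 1, 0] = structure[1, 1, 2] = False
    inner = mask & ~ndimage.binary_erosion(mask, structure=structure)
    outer = ndimage.binary_dilation(mask, structure=structure) & ~mask
    boundary = inner | outer
    rng = np.random.default_rng(perturbation.seed)
    flip = boundary & (rng.random(mask.shape) < perturbation.boundary_shift_prob)
    return mask ^ flip


def _ms(mean: float, sd: float) -> tuple[float, float]:
    if sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    return (mean, sd)


@dataclass(frozen=True)
class CohortDesign:
    """Generative model of one study cohort (healthy volunteers + PD).

    Defaults are the early-PD cohort: baseline group means/SDs from the
    cross-sectional results, programmed annualized rates from the
    longitudinal results, and per-subject rate SDs back-calculated from the
    published trial sample sizes. ``annual_rate_*`` are in %/yr on each
    measure's own percent-change scale (SNR rates act on SNR - 100).
    C_vol is derived as Vol/TIV: the female C_vol advantage and the
    amplified C_vol deficit emerge from the sex offset on TIV and the sex
    imbalance rather than being drawn independently.
    """

    n_hv: int = 41
    n_pd: int = 99
    cohort_label: str = "early"
    baseline_vol_hv_mm3: tuple[float, float] = (273.2, 48.4)
    pd_vol_deficit_frac: float = 0.112
    snr_hv: tuple[float, float] = (112.1, 1.6)
    snr_deficit_frac: float = 0.174
    cnr_hv: tuple[float, float] = (1.56, 0.23)
    cnr_deficit_frac: float = 0.203
    annual_rate_pd: Mapping[str, float] = field(
        default_factory=lambda: {"vol": -5.8, "snr": 1.5, "cnr": 1.9}
    )
    annual_rate_hv: Mapping[str, float] = field(
        default_factory=lambda: {"vol": 0.4, "snr": 0.8, "cnr": 3.9}
    )
    rate_sd: Mapping[str, float] = field(
        default_factory=lambda: {"vol": 4.1, "snr": 2.2, "cnr": 2.6}
    )
    sex_effect: Mapping[str, float] = field(default_factory=lambda: {"cnr": 0.10})
    scanner_offset: Mapping[str, float] = field(default_factory=dict)
    second_scanner_frac: float = 0.0
    scanner_labels: tuple[str, str] = ("PRISMA", "TRIO")
    tiv_mean_sd: tuple[float, float] = (1438.0, 120.0)
    tiv_sex_offset_cm3: float = 110.0
    visit_delay: tuple[float, float] = (2.0, 0.2)
    clinical_corr_rho: float = -0.4
    dropout_frac: float = 0.2
    hv_has_v2: bool = True
    p_male_pd: float = 0.667
    p_male_hv: float = 0.415
    age_mean_sd: tuple[float, float] = (61.0, 9.2)
    updrs_pd: tuple[float, float] = (30.3, 7.9)
    updrs_hv: tuple[float, float] = (5.7, 5.8)
    updrs_progression_per_yr: float = 1.65
    duration_pd_yr: tuple[float, float] = (1.5, 1.0)
    hy_pd: tuple[float, float] = (2.0, 0.2)
    ledd_pd_mg: tuple[float, float] = (309.0, 257.9)
    bnd_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hv < 2 or self.n_pd < 2:
            raise ValueError("need at least 2 subjects per group")
        for name in ("pd_vol_deficit_frac", "snr_deficit_frac", "cnr_deficit_frac",
                     "dropout_frac", "second_scanner_frac", "p_male_pd", "p_male_hv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not abs(self.clinical_corr_rho) < 1.0:
            raise ValueError("clinical correlation rho must satisfy |rho| < 1 "
                             "(correlation matrix infeasible otherwise)")
        for pair in (self.baseline_vol_hv_mm3, self.snr_hv, self.cnr_hv,
                     self.tiv_mean_sd, self.visit_delay, self.age_mean_sd,
                     self.updrs_pd, self.updrs_hv, self.duration_pd_yr,
                     self.hy_pd, self.ledd_pd_mg):
            _ms(*pair)

    @classmethod
    def early_pd(cls, **overrides) -> "CohortDesign":
        """Cohort of de-novo/early patients on the newer scanner (defaults)."""
        return cls(**overrides)

    @classmethod
    def progressing_pd(cls, **overrides) -> "CohortDesign":
        """Cohort of progressing patients (~9 yr duration) on the older scanner."""
        params = dict(
            n_hv=23,
            n_pd=41,
            cohort_label="progressing",
            baseline_vol_hv_mm3=(260.4, 37.0),
            pd_vol_deficit_frac=0.384,
            snr_hv=(109.8, 2.4),
            snr_deficit_frac=0.214,
            cnr_hv=(1.30, 0.39),
            cnr_deficit_frac=0.227,
            annual_rate_pd={"vol": -10.2, "snr": -3.7, "cnr": -3.0},
            visit_delay=(2.4, 0.5),
            dropout_frac=0.268,
            hv_has_v2=False,
            p_male_pd=0.659,
            p_male_hv=0.522,
            updrs_pd=(38.8, 10.8),
            duration_pd_yr=(9.3, 3.7),
            hy_pd=(2.0, 0.6),
            ledd_pd_mg=(761.3, 292.1),
            scanner_labels=("TRIO", "PRISMA"),
        )
        params.update(overrides)
        return cls(**params)


def _truncate(values: np.ndarray, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    return np.clip(values, lo, hi)


def generate_cohort(
    design: CohortDesign,
    phantom: PhantomSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: a subject-visit table and a matching phantom table.

    Returns ``(subjects, phantoms)``. ``subjects`` has one row per subject
    per retained visit with demographics, clinical scores and the
    generative (noise-free) measurement values; ``phantoms`` carries, for
    the same rows, the per-scan phantom parameters (per-side target volume,
    target SNR, background noise SD, render seed) from which images can be
    rendered and re-measured.
    """
    phantom = phantom or PhantomSpec()
    rng = np.random.default_rng(design.seed)
    n = design.n_hv + design.n_pd
    group = np.array(["HV"] * design.n_hv + ["PD"] * design.n_pd)
    is_pd = group == "PD"
    p_male = np.where(is_pd, design.p_male_pd, design.p_male_hv)
    sex = np.where(rng.random(n) < p_male, "M", "F")
    age = rng.normal(*design.age_mean_sd, size=n)
    scanner = np.where(
        rng.random(n) < design.second_scanner_frac,
        design.scanner_labels[1],
        design.scanner_labels[0],
    )
    on_second = scanner == design.scanner_labels[1]

    tiv = rng.normal(*design.tiv_mean_sd, size=n) + np.where(
        sex == "M", design.tiv_sex_offset_cm3 / 2.0, -design.tiv_sex_offset_cm3 / 2.0
    )
    tiv = _truncate(tiv, lo=900.0)

    vol_mu, vol_sd = design.baseline_vol_hv_mm3
    vol1 = rng.normal(vol_mu, vol_sd, size=n) - is_pd * design.pd_vol_deficit_frac * vol_mu
    vol1 = _truncate(vol1, lo=10.0 * phantom.voxel_volume_mm3)  # keep renderable

    snr_mu, snr_sd = design.snr_hv
    snr1 = rng.normal(snr_mu, snr_sd, size=n) - is_pd * design.snr_deficit_frac * (snr_mu - 100.0)
    snr1 = _truncate(snr1, lo=100.5)

    cnr_mu, cnr_sd = design.cnr_hv
    cnr1 = rng.normal(cnr_mu, cnr_sd, size=n) - is_pd * design.cnr_deficit_frac * cnr_mu
    for m, off in design.sex_effect.items():
        target = {"vol": vol1, "snr": snr1, "cnr": cnr1}.get(m)
        if target is not None:
            target += np.where(sex == "F", off, 0.0)
    for m, off in design.scanner_offset.items():
        target = {"vol": vol1, "snr": snr1, "cnr": cnr1}.get(m)
        if target is not None:
            target += np.where(on_second, off, 0.0)
    snr1 = _truncate(snr1, lo=100.5)
    cnr1 = _truncate(cnr1, lo=0.05)
    cvol1 = vol1 / tiv

    # --- follow-up ----------------------------------------------------------
    delay = _truncate(rng.normal(*design.visit_delay, size=n), lo=0.5)
    rate = {}
    for m in ("vol", "snr", "cnr"):
        mu = np.where(is_pd, design.annual_rate_pd[m], design.annual_rate_hv[m])
        rate[m] = mu + rng.normal(0.0, design.rate_sd[m], size=n)
    vol2 = _truncate(vol1 * (1.0 + rate["vol"] / 100.0 * delay), lo=0.0)
    snr2 = _truncate(snr1 + rate["snr"] / 100.0 * delay * (snr1 - 100.0), lo=100.1)
    cnr2 = _truncate(cnr1 * (1.0 + rate["cnr"] / 100.0 * delay), lo=0.05)
    cvol2 = vol2 / tiv

    retained = rng.random(n) >= design.dropout_frac
    if not design.hv_has_v2:
        retained &= is_pd

    # --- clinical scores ----------------------------------------------------
    # UPDRS correlated with baseline C_vol inside each group via the
    # bivariate-normal construction on the standardized C_vol.
    rho = design.clinical_corr_rho
    eps = rng.normal(size=n)
    updrs1 = np.empty(n)
    for grp, (mu, sd) in (("PD", design.updrs_pd), ("HV", design.updrs_hv)):
        sel = group == grp
        z = (cvol1[sel] - cvol1[sel].mean()) / max(cvol1[sel].std(), 1e-12)
        updrs1[sel] = mu + sd * (rho * z + np.sqrt(1.0 - rho**2) * eps[sel])
    updrs1 = _truncate(updrs1, lo=0.0)
    updrs2 = _truncate(
        updrs1 + design.updrs_progression_per_yr * delay + rng.normal(0.0, 2.0, size=n),
        lo=0.0,
    )
    duration1 = np.where(is_pd, _truncate(rng.normal(*design.duration_pd_yr, size=n), lo=0.1), np.nan)
    hy1 = np.where(is_pd, _truncate(rng.normal(*design.hy_pd, size=n), 0.0, 5.0), np.nan)
    ledd1 = np.where(is_pd, _truncate(rng.normal(*design.ledd_pd_mg, size=n), lo=0.0), np.nan)

    subject_id = np.array([f"{design.cohort_label[:1].upper()}{i:04d}" for i in range(n)])
    render_seeds = rng.integers(0, 2**31 - 1, size=(n, 2))

    rows, prows = [], []
    for i in range(n):
        visits = [("V1", vol1[i], cvol1[i], snr1[i], cnr1[i], updrs1[i], 0.0)]
        if retained[i]:
            visits.append(("V2", vol2[i], cvol2[i], snr2[i], cnr2[i], updrs2[i], delay[i]))
        for j, (visit, vol, cvol, snr, cnr, updrs, dly) in enumerate(visits):
            rows.append(
                dict(
                    subject_id=subject_id[i], visit=visit, group=group[i], sex=sex[i],
                    age=age[i] + (dly if visit == "V2" else 0.0), scanner=scanner[i],
                    delay_years=dly if visit == "V2" else np.nan, tiv_cm3=tiv[i],
                    vol_mm3=vol, cvol=cvol, snr=snr, cnr=cnr, updrs3_off=updrs,
                    disease_duration_yr=duration1[i] + dly if is_pd[i] else np.nan,
                    hy_stage=hy1[i], ledd_mg=ledd1[i],
                )
            )
            # phantom renders the target measures: per-side volume, SNR, and a
            # background SD chosen so the rendered CNR matches the target.
            bnd_sd = design.bnd_mean * (snr - 100.0) / 100.0 / cnr
            prows.append(
                dict(
                    subject_id=subject_id[i], visit=visit,
                    sn_target_volume=vol / 2.0, sn_target_snr=snr,
                    bnd_mean=design.bnd_mean, bnd_sd=bnd_sd,
                    n_sn_slices=phantom.n_sn_slices, render_seed=int(render_seeds[i, j]),
                )
            )
    subjects = pd.DataFrame(rows)
    phantoms = pd.DataFrame(prows)
    return subjects, phantoms
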