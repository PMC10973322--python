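"""Synthetic lower-leg CTA phantoms and cohort metadata.

The generator emulates the statistical structure a muscle-radiomics analysis
of peripheral arterial disease (PAD) assumes, without any patient data:

* two patient groups whose muscle-voxel HU differ in mean and dispersion
  (mild PAD: higher mean, lower coefficient of variation; severe PAD: lower
  mean, higher dispersion),
* correlated DSA/CTA runoff scores per group, with the mild/severe boundary
  at DSA score 7,
* stylized anatomy that stresses threshold segmentation: an elliptical
  subcutaneous-fat ring, two bones (cortical shell around a marrow core that
  falls inside the muscle HU window), contrast-filled arteries above the
  window, and veins inside the window that must be removed structurally.

Anatomy is a two-bone leg analog (tibia/fibula); only HU composition and
adjacency matter, not anatomical realism.  The leg tapers toward the ankle,
severe subjects carry a craniocaudal attenuation tilt (disease is usually
more expressed distally), and intramuscular partial-volume fat accumulates
distally with per-subject variability (myosteatosis), so that discrimination
between groups varies along the leg the way it does in real cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "SubjectRecord",
    "CTVolume",
    "TISSUE_LABELS",
    "generate_phantom",
    "sample_runoff_scores",
    "generate_cohort",
]

HU_MIN, HU_MAX = -1024, 3071

#: integer codes of the ground-truth tissue label map
TISSUE_LABELS = {
    "air": 0,
    "subcutaneous_fat": 1,
    "muscle": 2,
    "intramuscular_fat": 3,
    "cortical_bone": 4,
    "marrow": 5,
    "artery_contrast": 6,
    "vein": 7,
}


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue HU distribution (voxel-level mean and SD)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"tissue SD must be >= 0, got {self.sd}")


def _default_tissues() -> dict[str, TissueParams]:
    return {
        # muscle parameters reproduce the group-level values reported for
        # mild vs severe PAD lower-leg muscle (mean 44.6 vs 39.5 HU,
        # voxel SD 16.0 vs 16.7 HU)
        "muscle_mild": TissueParams(44.6, 16.0),
        "muscle_severe": TissueParams(39.5, 16.7),
        "subcutaneous_fat": TissueParams(-100.0, 15.0),
        # partial-volume fat streaks inside muscle: thin fat/muscle mixtures
        # land near 0 HU, i.e. *inside* the muscle threshold window
        "intramuscular_fat": TissueParams(0.0, 12.0),
        "cortical_bone": TissueParams(1200.0, 100.0),
        # marrow sits inside the [-10, 100] window and must be removed
        # structurally (enclosed by cortical bone)
        "marrow": TissueParams(30.0, 10.0),
        "artery_contrast": TissueParams(300.0, 30.0),
        # veins are inside the window too and must be removed structurally
        "vein": TissueParams(90.0, 10.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU parameters of the synthetic leg.

    ``between_subject_sd`` perturbs each subject's muscle HU mean around the
    group mean; defaults are back-computed from the reported interquartile
    ranges of the per-subject mean (mild 43.0-47.0, severe 37.0-43.5 HU,
    i.e. SD ~ IQR/1.349).  ``distal_gradient`` tilts severe subjects' muscle
    HU linearly from knee to ankle while preserving the whole-leg mean (the
    offset is centered at mid-leg); its per-subject SD models heterogeneity
    in lesion level.  ``distal_imf_*`` control a knee-to-ankle ramp of
    intramuscular partial-volume fat applied to both groups.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 60)
    spacing: tuple[float, float, float] = (3.0, 3.0, 5.0)
    tissue_params: dict[str, TissueParams] = field(default_factory=_default_tissues)
    imf_fraction: float = 0.04
    imf_fraction_sd: float = 0.02
    distal_gradient: float = -6.0
    distal_gradient_sd: float = 8.0
    distal_imf_max: float = 0.15
    distal_imf_sd: float = 0.12
    distal_imf_onset: float = 0.6
    between_subject_sd: tuple[float, float] = (3.0, 4.8)  # (mild, severe)
    between_subject_sd_of_sd: tuple[float, float] = (0.7, 0.8)  # (mild, severe)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 8 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if not 0.0 <= self.imf_fraction <= 1.0:
            raise ValueError(f"imf_fraction must be in [0, 1], got {self.imf_fraction}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in _default_tissues():
            if name not in self.tissue_params:
                raise ValueError(f"missing tissue_params entry: {name}")


@dataclass
class SubjectRecord:
    """One simulated limb: group label, runoff scores, optional covariates."""

    subject_id: str
    group: str
    dsa_score: float
    cta_score: float
    covariates: dict | None = None

    def __post_init__(self) -> None:
        if self.group not in ("mild", "severe"):
            raise ValueError(f"group must be 'mild' or 'severe', got {self.group!r}")
        for name, score in (("dsa_score", self.dsa_score), ("cta_score", self.cta_score)):
            if not 0.0 <= score <= 19.0:
                raise ValueError(f"{name} must be in [0, 19], got {score}")
        if (self.group == "mild") != (self.dsa_score <= 7):
            raise ValueError(
                f"group {self.group!r} inconsistent with dsa_score {self.dsa_score} "
                "(mild iff DSA score <= 7)"
            )


@dataclass
class CTVolume:
    """A 3D HU grid with voxel spacing; axis 2 runs knee -> ankle."""

    hu: np.ndarray
    spacing: tuple[float, float, float]
    knee_to_ankle: bool = True

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError("hu grid must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if self.hu.min() < HU_MIN or self.hu.max() > HU_MAX:
            raise ValueError("HU values outside the valid CT range [-1024, 3071]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape


def _subject_rng(spec_seed: int, subject_id: str) -> np.random.Generator:
    """Deterministic per-subject generator derived from (seed, subject_id)."""
    key = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed), key]))


def _disk(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, r: float) -> np.ndarray:
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _ellipse(xx, yy, cx, cy, rx, ry) -> np.ndarray:
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def build_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw the per-slice tissue label map (without intramuscular fat)."""
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    # subject-specific overall size jitter
    size = rng.uniform(0.92, 1.0)
    rx0, ry0 = 0.44 * nx * size, 0.40 * ny * size
    if cx - rx0 < 1 or cy - ry0 < 1:
        raise ValueError(
            f"leg outline (radii {rx0:.1f}, {ry0:.1f}) exceeds grid {spec.grid_shape[:2]}"
        )

    for z in range(nz):
        zt = z / max(nz - 1, 1)
        taper = 1.0 - 0.35 * zt  # leg narrows toward the ankle
        rx, ry = rx0 * taper, ry0 * taper
        fat_t = max(2.0, 0.12 * min(rx, ry))

        sl = np.zeros((nx, ny), dtype=np.uint8)
        leg = _ellipse(xx, yy, cx, cy, rx, ry)
        sl[leg] = TISSUE_LABELS["subcutaneous_fat"]
        muscle = _ellipse(xx, yy, cx, cy, rx - fat_t, ry - fat_t)
        sl[muscle] = TISSUE_LABELS["muscle"]

        # tibia analog: larger bone, anteromedial
        r_tib = max(3.0, 0.20 * rx)
        tx, ty = cx - 0.38 * rx, cy - 0.20 * ry
        tib = _disk(xx, yy, tx, ty, r_tib)
        sl[tib & muscle] = TISSUE_LABELS["cortical_bone"]
        marrow = _disk(xx, yy, tx, ty, max(1.0, r_tib - 2.0))
        sl[marrow & muscle] = TISSUE_LABELS["marrow"]

        # fibula analog: smaller bone, lateral
        r_fib = max(2.0, 0.10 * rx)
        fx, fy = cx + 0.52 * rx, cy + 0.30 * ry
        fib = _disk(xx, yy, fx, fy, r_fib)
        sl[fib & muscle] = TISSUE_LABELS["cortical_bone"]
        if r_fib >= 3.0:
            fmar = _disk(xx, yy, fx, fy, r_fib - 2.0)
            sl[fmar & muscle] = TISSUE_LABELS["marrow"]

        # vessels taper with the leg so their in-plane footprint stays a
        # small fraction of the shrinking muscle annulus
        vessel_r = max(1.0, 1.6 * taper)

        # three crural arteries (anterior/posterior tibial, peroneal analogs)
        in_muscle = sl == TISSUE_LABELS["muscle"]
        for ang in (0.35, 1.55, 2.65):
            ax = cx + 0.22 * rx * np.cos(ang + np.pi)
            ay = cy + 0.22 * ry * np.sin(ang + np.pi)
            art = _disk(xx, yy, ax, ay, vessel_r)
            sl[art & in_muscle] = TISSUE_LABELS["artery_contrast"]

        # paired veins wrapped in a fat sheath 2 voxels wider than the
        # lumen so the vein never touches muscle, even diagonally (real
        # veins run in fascial planes)
        in_muscle = sl == TISSUE_LABELS["muscle"]
        for ang in (0.9, 4.1):
            vx = cx + 0.30 * rx * np.cos(ang)
            vy = cy + 0.30 * ry * np.sin(ang)
            sheath = _disk(xx, yy, vx, vy, vessel_r + 2.0)
            vein = _disk(xx, yy, vx, vy, vessel_r)
            sl[sheath & in_muscle] = TISSUE_LABELS["subcutaneous_fat"]
            sl[vein & (sl == TISSUE_LABELS["subcutaneous_fat"])] = TISSUE_LABELS["vein"]

        labels[:, :, z] = sl
    return labels


def generate_phantom(
    spec: PhantomSpec,
    subject: SubjectRecord,
    return_labels: bool = False,
):
    """Render one subject's CTA volume (and optionally its tissue label map).

    Deterministic given ``(spec.seed, subject.subject_id)``.
    """
    rng = _subject_rng(spec.seed, subject.subject_id)
    labels = build_labels(spec, rng)
    nx, ny, nz = spec.grid_shape

    # intramuscular partial-volume fat: a flat base fraction plus a ramp that
    # grows from mid-leg to the ankle with per-subject magnitude
    muscle_mask = labels == TISSUE_LABELS["muscle"]
    zt = np.arange(nz) / max(nz - 1, 1)
    onset = spec.distal_imf_onset
    ramp = np.clip((zt - onset) / max(1.0 - onset, 1e-9), 0.0, 1.0)
    f_base = max(0.0, rng.normal(spec.imf_fraction, spec.imf_fraction_sd))
    f_distal = max(0.0, rng.normal(spec.distal_imf_max, spec.distal_imf_sd))
    frac_z = np.clip(f_base + f_distal * ramp, 0.0, 1.0)
    speckle = rng.random(spec.grid_shape) < frac_z[None, None, :]
    labels[muscle_mask & speckle] = TISSUE_LABELS["intramuscular_fat"]

    hu = np.full(spec.grid_shape, -1000.0)
    muscle_key = "muscle_mild" if subject.group == "mild" else "muscle_severe"
    group_idx = 0 if subject.group == "mild" else 1
    subj_offset = rng.normal(0.0, spec.between_subject_sd[group_idx])
    # per-subject voxel-level dispersion (patients differ in how heterogeneous
    # their muscle is, not just in its mean attenuation)
    sd_jitter = rng.normal(0.0, spec.between_subject_sd_of_sd[group_idx])

    for name, code in TISSUE_LABELS.items():
        if name == "air":
            continue
        key = muscle_key if name == "muscle" else name
        tp = spec.tissue_params[key]
        sd = max(tp.sd + sd_jitter, 0.0) if name == "muscle" else tp.sd
        sel = labels == code
        vals = rng.normal(tp.mean, sd, size=int(sel.sum()))
        hu[sel] = vals

    # subject-level perfusion offset on muscle only
    muscle_sel = labels == TISSUE_LABELS["muscle"]
    hu[muscle_sel] += subj_offset

    # severe subjects: centered knee->ankle tilt (whole-leg mean preserved);
    # gradient < 0 lowers distal HU
    if subject.group == "severe":
        g = rng.normal(spec.distal_gradient, spec.distal_gradient_sd)
        tilt = g * (zt - 0.5)
        hu[muscle_sel] += np.broadcast_to(tilt[None, None, :], hu.shape)[muscle_sel]

    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, size=hu.shape)

    hu = np.clip(np.rint(hu), HU_MIN, HU_MAX).astype(np.int16)
    vol = CTVolume(hu=hu, spacing=spec.spacing)
    if return_labels:
        return vol, labels
    return vol


# ---------------------------------------------------------------------------
# runoff-score simulation

#: group-conditional DSA score distributions (mean, SD) before truncation
DSA_PARAMS = {"mild": (3.3, 2.6), "severe": (12.3, 3.0)}
#: reported group-level CTA score means the offset calibration targets
CTA_TARGET_MEAN = {"mild": 6.1, "severe": 11.8}
#: free parameter: DSA/CTA score correlation
DSA_CTA_CORRELATION = 0.8


def _expected_dsa(group: str) -> tuple[float, float]:
    """Mean/SD of the truncated-and-clipped DSA sampler, computed analytically."""
    mu, sd = DSA_PARAMS[group]
    if sd == 0:
        return mu, 0.0
    if group == "mild":
        lo, hi = -np.inf, 7.0
        clip_lo, clip_hi = 0.0, 19.0
    else:
        lo, hi = 7.0, np.inf
        clip_lo, clip_hi = 0.0, 19.0
    a, b = (max(lo, -1e9) - mu) / sd, (min(hi, 1e9) - mu) / sd
    tn = stats.truncnorm(a, b, loc=mu, scale=sd)
    xs = np.linspace(tn.ppf(1e-9), tn.ppf(1 - 1e-9), 20001)
    clipped = np.clip(xs, clip_lo, clip_hi)
    pdf = tn.pdf(xs)
    m = np.trapezoid(clipped * pdf, xs)
    v = np.trapezoid((clipped - m) ** 2 * pdf, xs)
    return float(m), float(np.sqrt(max(v, 0.0)))


def sample_runoff_scores(group: str, seed_or_rng) -> tuple[float, float]:
    """Draw one (DSA, CTA) runoff-score pair for a subject of ``group``.

    DSA is drawn from the group-conditional normal, resampled until it falls
    on the correct side of the severity boundary (mild <= 7 < severe) and
    clipped to [0, 19].  CTA is DSA plus a Gaussian offset calibrated so the
    group CTA means match the reported values with correlation ~0.8.
    """
    if group not in DSA_PARAMS:
        raise ValueError(f"group must be 'mild' or 'severe', got {group!r}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    mu, sd = DSA_PARAMS[group]
    if sd == 0:
        dsa = float(np.clip(mu, 0.0, 19.0))
    else:
        for _ in range(10000):
            x = rng.normal(mu, sd)
            if (group == "mild" and x <= 7.0) or (group == "severe" and x > 7.0):
                break
        else:  # pragma: no cover - unreachable for sane parameters
            raise RuntimeError("runoff-score rejection sampling did not terminate")
        dsa = float(np.clip(x, 0.0, 19.0))

    e_dsa, sd_dsa = _expected_dsa(group)
    mu_off = CTA_TARGET_MEAN[group] - e_dsa
    rho = DSA_CTA_CORRELATION
    sd_off = sd_dsa * np.sqrt(max(1.0 / rho**2 - 1.0, 0.0))
    cta = float(np.clip(dsa + rng.normal(mu_off, sd_off), 0.0, 19.0))
    return dsa, cta


def generate_cohort(
    n_mild: int,
    n_severe: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir=None,
):
    """Simulate a cohort of subjects; optionally write volumes + CSV to disk.

    Returns ``(records, volumes)`` where ``volumes`` is a list of
    :class:`CTVolume` aligned with ``records``.  With ``out_dir`` set, each
    volume is written as NIfTI and a ``subjects.csv`` is emitted.
    """
    if n_mild < 1 or n_severe < 1:
        raise ValueError("n_mild and n_severe must be >= 1")
    spec = replace(spec if spec is not None else PhantomSpec(), seed=seed)

    records: list[SubjectRecord] = []
    for i in range(n_mild + n_severe):
        group = "mild" if i < n_mild else "severe"
        sid = f"{group}_{i:03d}"
        score_rng = _subject_rng(seed ^ 0x5C0FE, sid)
        dsa, cta = sample_runoff_scores(group, score_rng)
        records.append(SubjectRecord(subject_id=sid, group=group, dsa_score=dsa, cta_score=cta))

    volumes = [generate_phantom(spec, rec) for rec in records]

    if out_dir is not None:
        from . import io as ctio

        out = ctio.ensure_dir(out_dir)
        for rec, vol in zip(records, volumes):
            ctio.write_volume(out / f"{rec.subject_id}.nii.gz", vol)
        cohort_table(records).to_csv(out / "subjects.csv", index=False)
    return records, volumes


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "dsa_score": [r.dsa_score for r in records],
            "cta_score": [r.cta_score for r in records],
        }
    )
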