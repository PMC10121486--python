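"""Synthetic chest phantoms with panel votes and lung-function values.

The generator emulates the statistical structure of a state-aid applicant
cohort so that every downstream stage (segmentation, anomaly detection,
classification, fusion, agreement statistics) can be exercised end-to-end
without patient data:

* two ellipsoidal low-attenuation lungs inside a soft-tissue body,
* fibrosis-like reticular lesions (band-pass-filtered noise) placed
  preferentially peripheral and basal, with lesion burden proportional to a
  latent imaging severity in [0, 1],
* a three-rater panel whose votes are driven by a mix of imaging and
  functional severity plus independent per-rater noise (partial agreement),
* lung-function values (DLCO/FVC/VC as % predicted) that decline with a
  functional severity only partially coupled to the imaging severity, so
  the cohort-level DLCO-imaging correlation is weak by construction.

Default calibration (majority-verdict prevalence ~0.46, unanimity ~0.76,
DLCO-imaging r^2 ~0.28 over n = 500) is frozen in the module constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import ndtr

from .lung_function import LungFunctionRecord
from .panel import PanelVotes
from .volumes import Volume, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "SyntheticCase",
    "LESION_KINDS",
    "generate_volume",
    "simulate_lung_function",
    "simulate_panel",
    "draw_severities",
    "simulate_cohort_table",
    "generate_cohort",
]

LESION_KINDS = ("none", "asbestosis_fibrosis", "nonasbestos_ild", "plaques_only")

# --- frozen cohort calibration -------------------------------------------
P_HEALTHY = 0.30          # fraction of cases with zero imaging severity
RHO = 0.5                 # imaging share of the functional severity
VOTE_IMG_WEIGHT = 0.7     # imaging share of the panel vote score
VOTE_TAU = 0.40           # default vote threshold (prevalence ~0.46)
RATER_NOISE_SD = 0.15     # per-rater vote noise (unanimity ~0.76)
MAX_LESION_FRACTION = 0.25  # lung fraction lesioned at severity 1

DLCO_SLOPE = 55.0
DLCO_NOISE_SD = 12.0
FVC_SLOPE = 30.0
FVC_NOISE_SD = 15.0
VC_SLOPE = 25.0
VC_NOISE_SD = 15.0
LF_CLIP = (15.0, 130.0)

# attenuation defaults (HU)
AIR_HU = -1024.0
FIBROSIS_HU = -150.0
PLAQUE_HU = 150.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single phantom volume."""

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    lung_hu: float = -800.0
    body_hu: float = 40.0
    noise_sd: float = 20.0
    lesion_kind: str = "none"
    severity_img: float = 0.0
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s < 8 for s in shape):
            raise ValueError(f"grid_shape must be three integers >= 8, got {self.grid_shape}")
        object.__setattr__(self, "grid_shape", shape)
        if self.lesion_kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion_kind {self.lesion_kind!r}; expected one of {LESION_KINDS}")
        if not 0.0 <= self.severity_img <= 1.0:
            raise ValueError(f"severity_img must be in [0, 1], got {self.severity_img}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticCase:
    """One phantom with its ground truth and simulated clinical data."""

    case_id: str
    volume: Volume
    lesion_mask: np.ndarray
    lung_mask: np.ndarray
    lesion_kind: str
    severity_img: float
    severity_func: float
    lung_function: LungFunctionRecord
    votes: PanelVotes

    @property
    def verdict(self) -> bool:
        return self.votes.verdict


def _lung_geometry(shape):
    """Boolean body and lung masks for the two-ellipsoid phantom."""
    nx, ny, nz = shape
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    body = (x / 0.95) ** 2 + (y / 0.85) ** 2 + z**2 <= 1.0
    lungs = np.zeros(shape, dtype=bool)
    for cx in (-0.42, 0.42):
        lungs |= ((x - cx) / 0.30) ** 2 + ((y + 0.05) / 0.55) ** 2 + (z / 0.72) ** 2 <= 1.0
    return body, lungs & body


def _bandpass_texture(shape, rng):
    noise = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(noise, 1.0) - ndimage.gaussian_filter(noise, 3.0)
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _lesion_bias(lungs, kind):
    """Spatial placement prior: peripheral+basal for asbestosis, central+apical otherwise."""
    dist = ndimage.distance_transform_edt(lungs)
    dmax = dist.max()
    d_norm = dist / dmax if dmax > 0 else dist
    nz = lungs.shape[2]
    zn = np.broadcast_to(np.arange(nz) / max(nz - 1, 1), lungs.shape)
    if kind == "nonasbestos_ild":
        return 0.6 * d_norm + 0.4 * zn
    return 0.6 * (1.0 - d_norm) + 0.4 * (1.0 - zn)


def generate_volume(spec: PhantomSpec) -> tuple[Volume, np.ndarray]:
    """Build one phantom volume (HU) and its parenchymal lesion mask.

    Deterministic for a fixed spec (including seed).  The lesion voxel count
    equals ``round(severity_img * MAX_LESION_FRACTION * n_lung_voxels)`` so
    lesion burden is exactly monotone in severity.  Pleural plaques
    (``plaques_only``) raise attenuation on a thin shell just outside the
    lung boundary and leave the parenchymal lesion mask empty.
    """
    rng = np.random.default_rng(spec.seed)
    body, lungs = _lung_geometry(spec.grid_shape)

    values = np.full(spec.grid_shape, AIR_HU, dtype=np.float64)
    values[body] = spec.body_hu
    values[lungs] = spec.lung_hu
    if spec.noise_sd > 0:
        values[body] += rng.normal(0.0, spec.noise_sd, size=int(body.sum()))

    lesion = np.zeros(spec.grid_shape, dtype=bool)
    texture = _bandpass_texture(spec.grid_shape, rng)

    if spec.lesion_kind in ("asbestosis_fibrosis", "nonasbestos_ild"):
        n_target = int(round(spec.severity_img * MAX_LESION_FRACTION * lungs.sum()))
        if n_target > 0:
            score = texture + 1.5 * _lesion_bias(lungs, spec.lesion_kind)
            flat = np.flatnonzero(lungs)
            order = np.argsort(-score.ravel()[flat], kind="stable")
            lesion.ravel()[flat[order[:n_target]]] = True
            values[lesion] = FIBROSIS_HU + 60.0 * texture[lesion]
    elif spec.lesion_kind == "plaques_only" and spec.severity_img > 0:
        shell = ndimage.binary_dilation(lungs) & ~lungs & body
        cover = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), 2.0)
        thr = np.quantile(cover[shell], 1.0 - spec.severity_img) if shell.any() else np.inf
        values[shell & (cover >= thr)] = PLAQUE_HU

    # desk-scale spacing: ~34 cm field of view, 29 cm cranio-caudal coverage
    spacing = tuple(340.0 / s for s in spec.grid_shape[:2]) + (288.0 / spec.grid_shape[2],)
    return Volume(values, spacing), lesion


def simulate_lung_function(
    severity_img: float,
    severity_func: float,
    seed: int,
    dlco_slope: float = DLCO_SLOPE,
    dlco_noise_sd: float = DLCO_NOISE_SD,
    fvc_slope: float = FVC_SLOPE,
    fvc_noise_sd: float = FVC_NOISE_SD,
    vc_slope: float = VC_SLOPE,
    vc_noise_sd: float = VC_NOISE_SD,
) -> LungFunctionRecord:
    """Draw DLCO/FVC/VC (% predicted) declining linearly in functional severity.

    Only ``severity_func`` enters the formulas; the weak cohort-level coupling
    between lung function and imaging arises from how ``severity_func`` is
    drawn (see :func:`draw_severities`), not from this function.
    """
    if not (0.0 <= severity_img <= 1.0 and 0.0 <= severity_func <= 1.0):
        raise ValueError("severities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = LF_CLIP
    dlco = float(np.clip(100.0 - dlco_slope * severity_func + rng.normal(0, dlco_noise_sd), lo, hi))
    fvc = float(np.clip(100.0 - fvc_slope * severity_func + rng.normal(0, fvc_noise_sd), lo, hi))
    vc = float(np.clip(100.0 - vc_slope * severity_func + rng.normal(0, vc_noise_sd), lo, hi))
    return LungFunctionRecord(vc_pct=vc, fvc_pct=fvc, dlco_pct=dlco)


def simulate_panel(
    severity_img: float,
    severity_func: float,
    seed: int,
    img_weight: float = VOTE_IMG_WEIGHT,
    tau: float = VOTE_TAU,
    noise_scale: float = RATER_NOISE_SD,
) -> PanelVotes:
    """Three raters vote positive iff the shared severity score plus their
    private Gaussian noise exceeds the threshold ``tau``."""
    if not (0.0 <= severity_img <= 1.0 and 0.0 <= severity_func <= 1.0):
        raise ValueError("severities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    score = img_weight * severity_img + (1.0 - img_weight) * severity_func
    eps = rng.normal(0.0, noise_scale, size=3) if noise_scale > 0 else np.zeros(3)
    return PanelVotes(tuple(int(score + e > tau) for e in eps))


def draw_severities(n: int, rng: np.random.Generator, p_healthy: float = P_HEALTHY, rho: float = RHO):
    """Draw latent imaging and functional severities for ``n`` cases.

    A fraction ``p_healthy`` has zero imaging severity; the rest are uniform
    on [0.05, 1].  The functional severity mixes the imaging severity with an
    independent latent, ``rho * s_img + (1 - rho) * u``, which is the single
    knob decoupling lung function from imaging.
    """
    healthy = rng.uniform(size=n) < p_healthy
    s_img = np.where(healthy, 0.0, rng.uniform(0.05, 1.0, size=n))
    u = rng.uniform(size=n)
    return s_img, rho * s_img + (1.0 - rho) * u


def _solve_tau(vote_scores: np.ndarray, prevalence_target: float, noise_scale: float) -> float:
    """Vote threshold giving the target expected majority-verdict prevalence."""
    def expected_prevalence(tau):
        p = ndtr((vote_scores - tau) / noise_scale) if noise_scale > 0 else (vote_scores > tau).astype(float)
        return float(np.mean(p**3 + 3 * p**2 * (1 - p)))

    lo, hi = -1.0, 2.0
    if expected_prevalence(lo) < prevalence_target or expected_prevalence(hi) > prevalence_target:
        raise ValueError(f"prevalence target {prevalence_target} unreachable")
    return float(brentq(lambda t: expected_prevalence(t) - prevalence_target, lo, hi, xtol=1e-6))


def simulate_cohort_table(
    n: int,
    prevalence_target: float = 0.46,
    seed: int = 0,
    p_healthy: float = P_HEALTHY,
    rho: float = RHO,
    img_weight: float = VOTE_IMG_WEIGHT,
    noise_scale: float = RATER_NOISE_SD,
) -> pd.DataFrame:
    """Simulate the clinical table of a cohort (no volumes).

    Assigns a lesion kind per case — mostly asbestosis-like fibrosis, with a
    small admixture of non-asbestos interstitial disease (whose imaging the
    panel discounts when voting on asbestosis) and of pleural-plaques-only
    cases among the unaffected — then draws votes and lung function.  The
    vote threshold is solved so the expected majority prevalence matches the
    target; rater noise is untouched, so unanimity stays at its calibrated
    level.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    s_img, s_func = draw_severities(n, rng, p_healthy=p_healthy, rho=rho)

    kinds = np.where(s_img > 0, "asbestosis_fibrosis", "none").astype(object)
    r = rng.uniform(size=n)
    kinds[(s_img > 0) & (r < 0.05)] = "nonasbestos_ild"
    plaque = (s_img == 0) & (r < 0.10)
    kinds[plaque] = "plaques_only"
    # plaque extent re-uses the imaging-severity knob but is not parenchymal
    s_img = np.where(plaque, rng.uniform(0.2, 0.8, size=n), s_img)

    # the panel votes on *asbestosis*: non-asbestos patterns are heavily
    # discounted, plaques and healthy lungs carry no parenchymal signal
    s_vote = np.where(kinds == "asbestosis_fibrosis", s_img, 0.0)
    s_vote = np.where(kinds == "nonasbestos_ild", 0.15 * s_img, s_vote)
    # functional severity follows the parenchymal disease, whatever its kind
    parenchymal = np.isin(kinds, ("asbestosis_fibrosis", "nonasbestos_ild"))
    s_func = np.where(parenchymal, s_func, (1.0 - rho) * rng.uniform(size=n))

    vote_scores = img_weight * s_vote + (1.0 - img_weight) * s_func
    tau = _solve_tau(vote_scores, prevalence_target, noise_scale)
    eps = rng.normal(0.0, noise_scale, size=(n, 3))
    votes = (vote_scores[:, None] + eps > tau).astype(int)

    lf_seeds = rng.integers(0, 2**31 - 1, size=n)
    records = [simulate_lung_function(si, sf, int(sd)) for si, sf, sd in zip(s_img, s_func, lf_seeds)]

    return pd.DataFrame(
        {
            "case_id": [f"case_{i:04d}" for i in range(n)],
            "lesion_kind": kinds,
            "severity_img": s_img,
            "severity_func": s_func,
            "vc_pct": [r.vc_pct for r in records],
            "fvc_pct": [r.fvc_pct for r in records],
            "dlco_pct": [r.dlco_pct for r in records],
            "vote1": votes[:, 0],
            "vote2": votes[:, 1],
            "vote3": votes[:, 2],
        }
    )


def generate_cohort(
    n: int,
    prevalence_target: float = 0.46,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (48, 48, 24),
    out_dir=None,
) -> list[SyntheticCase]:
    """Generate ``n`` phantom cases (volumes + clinical table).

    With ``out_dir`` set, writes one NIfTI volume and one NIfTI lesion mask
    per case plus ``cohort.csv``; always returns the in-memory cases.
    """
    table = simulate_cohort_table(n, prevalence_target=prevalence_target, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    case_seeds = rng.integers(0, 2**31 - 1, size=n)

    cases = []
    for i, row in table.iterrows():
        spec = PhantomSpec(
            grid_shape=grid_shape,
            lesion_kind=row["lesion_kind"],
            severity_img=float(row["severity_img"]),
            seed=int(case_seeds[i]),
        )
        volume, lesion = generate_volume(spec)
        _, lungs = _lung_geometry(grid_shape)
        cases.append(
            SyntheticCase(
                case_id=row["case_id"],
                volume=volume,
                lesion_mask=lesion,
                lung_mask=lungs,
                lesion_kind=row["lesion_kind"],
                severity_img=float(row["severity_img"]),
                severity_func=float(row["severity_func"]),
                lung_function=LungFunctionRecord(
                    vc_pct=row["vc_pct"], fvc_pct=row["fvc_pct"], dlco_pct=row["dlco_pct"]
                ),
                votes=PanelVotes((int(row["vote1"]), int(row["vote2"]), int(row["vote3"]))),
            )
        )

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for case in cases:
            write_volume(case.volume, out / f"{case.case_id}.nii.gz")
            write_mask(case.lesion_mask, out / f"{case.case_id}_lesion.nii.gz", case.volume.spacing)
        table.to_csv(out / "cohort.csv", index=False)

    return cases
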