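"""Digital chest phantoms, simulated reconstruction kernels, and survival
cohorts with emphysema-dependent mortality.

These generators are first-class study material, not test scaffolding: the
phantom carries exact ground truth (lung mask, emphysema cluster mask), the
kernel simulator reproduces the band-energy signature of soft versus sharp
reconstruction filters and of slice-thickness averaging, and the cohort
simulator reproduces the case-control sampling design of a screening study
(every death kept, survivors subsampled with inverse-fraction weights).

A phantom is two ellipsoidal lungs inside a soft-tissue cylinder inside
exterior air. The parenchyma carries Gaussian texture around -860 HU;
emphysematous regions are non-overlapping spheres at -985 HU. A "soft"
kernel is a Gaussian blur, a "sharp" kernel an unsharp-mask boost plus
white noise; each rendition is then slab-averaged to its slice thickness.
Kernel simulation is appearance-level (blur/boost/noise), not
projection-domain CT physics: it reproduces the frequency-band energy
differences that kernel normalization targets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .emphysema_quant import (
    QuantConfig,
    ReferenceEnergyProfile,
    compute_norm_es,
    compute_orig_es,
    compute_reference_profile,
    resample_mask_z,
    resample_z,
)
from .survival_stats import Cohort
from .volume_io import HU_MAX, HU_MIN, CTVolume, LungMask

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phantom


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of a digital chest phantom."""

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = (1.25, 1.0, 1.0)
    body_hu: float = 40.0
    parenchyma_hu: float = -860.0
    texture_sd_hu: float = 40.0
    n_clusters: int = 8
    cluster_radius_mm: tuple[float, float] = (3.5, 9.0)
    cluster_hu: float = -995.0
    exterior_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.cluster_hu < -950.0 < self.parenchyma_hu):
            raise ValueError("need cluster_hu < -950 < parenchyma_hu")
        lo, hi = self.cluster_radius_mm
        if lo <= 0 or hi < lo:
            raise ValueError("cluster radius range must be positive and ordered")
        if self.texture_sd_hu < 0 or self.n_clusters < 0:
            raise ValueError("texture_sd_hu and n_clusters must be >= 0")


# lung ellipsoids: (centre z,y,x mm fractions of extent, semi-axes mm)
_LUNGS = (
    ((0.5, 0.52, 0.30), (0.38, 0.27, 0.18)),
    ((0.5, 0.52, 0.70), (0.38, 0.27, 0.18)),
)


def _phantom_geometry(spec: PhantomSpec):
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    ext = (nz * sz, ny * sy, nx * sx)
    zz = (np.arange(nz) + 0.5) * sz
    yy = (np.arange(ny) + 0.5) * sy
    xx = (np.arange(nx) + 0.5) * sx
    lungs = []
    for (fc, fr) in _LUNGS:
        centre = tuple(f * e for f, e in zip(fc, ext))
        semi = tuple(f * min(ext[1], ext[2]) for f in fr)
        lungs.append((centre, semi))
    return (zz, yy, xx), ext, lungs


def _ellipsoid_mask(coords, centre, semi) -> np.ndarray:
    zz, yy, xx = coords
    q = (
        ((zz - centre[0]) / semi[0])[:, None, None] ** 2
        + ((yy - centre[1]) / semi[1])[None, :, None] ** 2
        + ((xx - centre[2]) / semi[2])[None, None, :] ** 2
    )
    return q <= 1.0


def _place_clusters(spec: PhantomSpec, lungs, rng: np.random.Generator):
    """Rejection-sample non-overlapping spheres fully inside the lungs."""
    placed: list[tuple[np.ndarray, float]] = []
    lo, hi = spec.cluster_radius_mm
    attempts = 0
    max_attempts = 2000 * max(1, spec.n_clusters)
    while len(placed) < spec.n_clusters and attempts < max_attempts:
        attempts += 1
        centre_l, semi = lungs[rng.integers(len(lungs))]
        r = float(rng.uniform(lo, hi))
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) > 1.0:
            continue
        c = np.asarray(centre_l) + u * np.asarray(semi)
        # conservative containment: shrink the ellipsoid by r / smallest axis
        margin = 1.0 - r / min(semi)
        if margin <= 0 or np.sum(((c - centre_l) / semi) ** 2) > margin**2:
            continue
        if any(np.linalg.norm(c - c2) <= r + r2 for c2, r2 in placed):
            continue
        placed.append((c, r))
    if len(placed) < spec.n_clusters:
        log.warning("placed only %d of %d clusters", len(placed), spec.n_clusters)
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LungMask, np.ndarray]:
    """Render a phantom; returns the clean volume, the ground-truth lung
    mask and the ground-truth emphysema grid (uint8)."""
    rng = np.random.default_rng(spec.seed)
    coords, ext, lungs = _phantom_geometry(spec)
    zz, yy, xx = coords

    vox = np.full(spec.shape, spec.exterior_hu, dtype=np.float64)
    body_r = 0.46 * min(ext[1], ext[2])
    body = (
        ((yy - 0.5 * ext[1]) ** 2)[None, :, None]
        + ((xx - 0.5 * ext[2]) ** 2)[None, None, :]
    ) <= body_r**2
    body = np.broadcast_to(body, spec.shape)
    vox[body] = spec.body_hu

    lung_mask = np.zeros(spec.shape, dtype=bool)
    for centre, semi in lungs:
        lung_mask |= _ellipsoid_mask(coords, centre, semi)

    texture = rng.normal(0.0, spec.texture_sd_hu, size=spec.shape) if spec.texture_sd_hu > 0 else 0.0
    vox[lung_mask] = spec.parenchyma_hu
    if spec.texture_sd_hu > 0:
        vox[lung_mask] += texture[lung_mask]

    emph = np.zeros(spec.shape, dtype=bool)
    for c, r in _place_clusters(spec, lungs, rng):
        d2 = (
            ((zz - c[0]) ** 2)[:, None, None]
            + ((yy - c[1]) ** 2)[None, :, None]
            + ((xx - c[2]) ** 2)[None, None, :]
        )
        emph |= d2 <= r**2
    emph &= lung_mask
    vox[emph] = spec.cluster_hu

    np.clip(vox, HU_MIN, HU_MAX, out=vox)
    volume = CTVolume(vox.astype(np.float32), spec.spacing)
    mask = LungMask(lung_mask.astype(np.uint8), spec.spacing)
    return volume, mask, emph.astype(np.uint8)


def true_emphysema_fraction(mask: LungMask, emphysema_truth: np.ndarray) -> float:
    """Exact ground-truth emphysema percentage of the lung."""
    return 100.0 * float(emphysema_truth.sum()) / mask.n_voxels


# ---------------------------------------------------------------------------
# kernel simulation


@dataclass
class KernelSim:
    """Appearance-level reconstruction-kernel model.

    kind : label (soft/medium/sharp).
    blur_sigma_mm : Gaussian smoothing (soft kernels).
    boost, boost_sigma_mm : unsharp-mask high-frequency amplification
        (sharp kernels): ``I + boost * (I - G_sigma(I))``.
    noise_sd_hu : additive white reconstruction noise.
    slice_thickness_mm : slab-averaged output thickness.
    """

    kind: str
    blur_sigma_mm: float = 0.0
    boost: float = 0.0
    boost_sigma_mm: float = 1.0
    noise_sd_hu: float = 0.0
    slice_thickness_mm: float = 1.25

    def __post_init__(self) -> None:
        if self.blur_sigma_mm < 0 or self.noise_sd_hu < 0:
            raise ValueError("blur sigma and noise sd must be >= 0")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be > 0")


#: Default kernel set spanning the soft-to-sharp range of screening scans,
#: including the thick-soft and thin-sharp combinations.
DEFAULT_KERNELS: dict[str, KernelSim] = {
    "soft": KernelSim("soft", blur_sigma_mm=1.0, noise_sd_hu=5.0, slice_thickness_mm=4.0),
    "medium": KernelSim("medium", blur_sigma_mm=0.5, noise_sd_hu=12.0, slice_thickness_mm=2.0),
    "sharp": KernelSim("sharp", boost=0.8, boost_sigma_mm=1.0, noise_sd_hu=20.0,
                       slice_thickness_mm=1.25),
}


def simulate_kernel(clean: CTVolume, sim: KernelSim, seed: int = 0) -> CTVolume:
    """Render the clean phantom under a kernel model: blur and/or unsharp
    boost, white noise, then z slab-averaging to the stated thickness."""
    rng = np.random.default_rng(seed)
    arr = clean.voxels.astype(np.float64)
    out = arr
    if sim.blur_sigma_mm > 0:
        out = ndimage.gaussian_filter(
            arr, sigma=[sim.blur_sigma_mm / s for s in clean.spacing], mode="nearest"
        )
    if sim.boost > 0:
        low = ndimage.gaussian_filter(
            arr, sigma=[sim.boost_sigma_mm / s for s in clean.spacing], mode="nearest"
        )
        out = out + sim.boost * (arr - low)
    if sim.noise_sd_hu > 0:
        out = out + rng.normal(0.0, sim.noise_sd_hu, size=arr.shape)
    np.clip(out, HU_MIN, HU_MAX, out=out)
    vol = CTVolume(out.astype(np.float32), clean.spacing, clean.origin)
    if sim.slice_thickness_mm != clean.spacing[0]:
        vol, _ = resample_z(vol, None, sim.slice_thickness_mm)
    return vol


def render_phantom(clean: CTVolume, mask: LungMask, sim: KernelSim,
                   seed: int = 0) -> tuple[CTVolume, LungMask]:
    """Kernel rendition plus the ground-truth mask carried to the rendition
    grid by the same slab averaging."""
    vol = simulate_kernel(clean, sim, seed)
    out_mask = (resample_mask_z(mask, sim.slice_thickness_mm)
                if sim.slice_thickness_mm != mask.spacing[0] else mask)
    return vol, out_mask


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class MarkerNoise:
    """Additive bias and noise a kernel imposes on the raw density-mask score."""

    bias: float
    sd: float


@dataclass
class CohortSimSpec:
    """Generative model of a screening cohort with emphysema-driven mortality.

    True emphysema extent is a right-skewed mixture (a near-zero half-normal
    mass plus a gamma tail). Death times are exponential with hazard
    ``baseline_hazard * exp(log_hazard_slope * trueES)``; censoring is the
    minimum of the administrative end of follow-up and, for a small
    fraction, a uniform early drop-out. Observed origES adds a
    kernel-dependent bias and noise; observed normES adds only small noise.
    The case-control stage keeps all deaths and samples a fraction of
    survivors, giving them weight 1/fraction.
    """

    n_subjects: int = 2000
    baseline_hazard_per_day: float = 6.5e-5
    log_hazard_slope: float = 0.30
    admin_censor_day: float = 2600.0  # just over seven years of follow-up
    early_censor_frac: float = 0.05
    zero_mass_frac: float = 0.6
    zero_mass_sd: float = 0.4
    gamma_shape: float = 1.2
    gamma_scale: float = 5.0
    lung_cancer_base: float = 0.15
    lung_cancer_slope: float = 0.02
    kernel_noise: dict = field(default_factory=lambda: {
        "soft": MarkerNoise(bias=-1.0, sd=1.0),
        "medium": MarkerNoise(bias=1.5, sd=1.5),
        "sharp": MarkerNoise(bias=8.0, sd=2.5),
    })
    norm_noise_sd: float = 0.4
    control_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if self.baseline_hazard_per_day <= 0:
            raise ValueError("baseline hazard must be > 0")
        for name, frac in (("early_censor_frac", self.early_censor_frac),
                           ("control_fraction", self.control_fraction)):
            if not (0 < frac <= 1) and not (name == "early_censor_frac" and frac == 0):
                raise ValueError(f"{name} must lie in (0, 1]")


def _draw_true_es(n: int, spec: CohortSimSpec, rng: np.random.Generator) -> np.ndarray:
    zero = rng.random(n) < spec.zero_mass_frac
    es = np.where(
        zero,
        np.abs(rng.normal(0.0, spec.zero_mass_sd, n)),
        rng.gamma(spec.gamma_shape, spec.gamma_scale, n),
    )
    return es


def _survival_outcomes(true_es: np.ndarray, spec: CohortSimSpec,
                       rng: np.random.Generator):
    n = true_es.size
    lam = spec.baseline_hazard_per_day * np.exp(spec.log_hazard_slope * true_es)
    death_time = rng.exponential(1.0 / lam)
    censor_time = np.full(n, spec.admin_censor_day)
    early = rng.random(n) < spec.early_censor_frac
    censor_time[early] = rng.uniform(1.0, spec.admin_censor_day, early.sum())
    time = np.minimum(death_time, censor_time)
    event = (death_time <= censor_time).astype(int)
    p_lc = np.clip(spec.lung_cancer_base + spec.lung_cancer_slope * true_es, 0.0, 0.8)
    event_lc = event * (rng.random(n) < p_lc).astype(int)
    return np.maximum(time, 1.0), event, event_lc


def _case_control(frame: pd.DataFrame, true_es: np.ndarray, spec: CohortSimSpec,
                  rng: np.random.Generator):
    if spec.control_fraction >= 1.0:
        frame = frame.assign(weight=1.0)
        return Cohort(frame, design="full"), true_es
    alive = frame["event_all_cause"].to_numpy() == 0
    keep_alive = alive & (rng.random(len(frame)) < spec.control_fraction)
    keep = ~alive | keep_alive
    frame = frame.loc[keep].copy()
    frame["weight"] = np.where(frame["event_all_cause"] == 1, 1.0,
                               1.0 / spec.control_fraction)
    cohort = Cohort(frame, design="case_control",
                    control_fraction=spec.control_fraction)
    return cohort, true_es[keep.to_numpy() if hasattr(keep, "to_numpy") else keep]


def simulate_cohort(spec: CohortSimSpec) -> tuple[Cohort, np.ndarray]:
    """Simulate a case-control screening cohort; returns the cohort and the
    true emphysema extent of the retained subjects."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    true_es = _draw_true_es(n, spec, rng)
    time, event, event_lc = _survival_outcomes(true_es, spec, rng)

    kernels = list(spec.kernel_noise)
    assigned = rng.integers(len(kernels), size=n)
    bias = np.array([spec.kernel_noise[kernels[k]].bias for k in assigned])
    sd = np.array([spec.kernel_noise[kernels[k]].sd for k in assigned])
    orig_es = np.maximum(true_es + bias + rng.normal(0.0, 1.0, n) * sd, 0.0)
    norm_es = np.maximum(true_es + rng.normal(0.0, spec.norm_noise_sd, n), 0.0)

    frame = pd.DataFrame({
        "id": [f"s{i:06d}" for i in range(n)],
        "time_days": time,
        "event_all_cause": event,
        "event_lung_cancer": event_lc,
        "weight": 1.0,
        "kernel": [kernels[k] for k in assigned],
        "origES": orig_es,
        "normES": norm_es,
    })
    return _case_control(frame, true_es, spec, rng)


# ---------------------------------------------------------------------------
# end-to-end fixture


@dataclass
class EndToEndFixture:
    """Phantom scores, reference profile and an imaging-driven cohort."""

    phantom_scores: pd.DataFrame  # phantom, kernel, true_es, orig_es, norm_es
    profile: ReferenceEnergyProfile
    cohort: Cohort
    true_es: np.ndarray
    seed: int


def score_phantom_set(seed: int, n_phantoms: int = 20,
                      kernels: dict[str, KernelSim] | None = None,
                      quant_config: QuantConfig | None = None,
                      reference_kernel: str = "medium",
                      n_reference: int = 5,
                      phantom_shape: tuple[int, int, int] = (64, 96, 96),
                      ) -> tuple[pd.DataFrame, ReferenceEnergyProfile]:
    """Generate ``n_phantoms`` phantoms with varying emphysema burden,
    render each under every kernel, and score origES/normES against a
    reference profile computed from the reference-kernel renditions of the
    first ``n_reference`` phantoms."""
    kernels = kernels or DEFAULT_KERNELS
    config = quant_config or QuantConfig()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=(n_phantoms, 1 + len(kernels)))

    phantoms = []
    for p in range(n_phantoms):
        spec = PhantomSpec(shape=phantom_shape,
                           n_clusters=int(rng.integers(0, 26)),
                           seed=int(child_seeds[p, 0]))
        clean, mask, emph = generate_phantom(spec)
        phantoms.append((clean, mask, true_emphysema_fraction(mask, emph)))

    ref_sim = kernels[reference_kernel]
    ref_vols, ref_masks = [], []
    for p in range(min(n_reference, n_phantoms)):
        clean, mask, _ = phantoms[p]
        vol, rmask = render_phantom(clean, mask, ref_sim, seed=int(child_seeds[p, 1]))
        ref_vols.append(vol)
        ref_masks.append(rmask)
    profile = compute_reference_profile(ref_vols, ref_masks, config)

    rows = []
    for p, (clean, mask, t_es) in enumerate(phantoms):
        for k, (name, sim) in enumerate(kernels.items()):
            vol, rmask = render_phantom(clean, mask, sim,
                                        seed=int(child_seeds[p, 1 + k]))
            orig = compute_orig_es(vol, rmask, config)
            norm = compute_norm_es(vol, rmask, profile, config)
            rows.append({"phantom": p, "kernel": name, "true_es": t_es,
                         "orig_es": orig.score, "norm_es": norm.score})
    return pd.DataFrame(rows), profile


def end_to_end_fixture(seed: int, n_phantoms: int = 20, n_subjects: int = 2000,
                       cohort_spec: CohortSimSpec | None = None,
                       outdir=None, **score_kwargs) -> EndToEndFixture:
    """The demo dataset: score a phantom set under three kernels, then build
    a case-control cohort whose subjects each carry the *measured*
    origES/normES of one (phantom, kernel) rendition and whose survival is
    driven by that phantom's true emphysema extent."""
    scores, profile = score_phantom_set(seed, n_phantoms=n_phantoms, **score_kwargs)
    # The phantom set carries more emphysema than the parametric true-ES
    # mixture, so the baseline hazard is set lower here to keep the deceased
    # share of the cohort near the ~30% typical of a screening case mix.
    spec = cohort_spec or CohortSimSpec(n_subjects=n_subjects, seed=seed,
                                        baseline_hazard_per_day=1.2e-5)
    rng = np.random.default_rng(spec.seed + 1)

    by_pk = scores.set_index(["phantom", "kernel"])
    kernels = sorted(scores["kernel"].unique().tolist())
    pi = rng.integers(n_phantoms, size=spec.n_subjects)
    ki = rng.integers(len(kernels), size=spec.n_subjects)
    true_es = scores.drop_duplicates("phantom").set_index("phantom")["true_es"].loc[pi].to_numpy()
    orig_es = np.array([by_pk.loc[(p, kernels[k]), "orig_es"] for p, k in zip(pi, ki)])
    norm_es = np.array([by_pk.loc[(p, kernels[k]), "norm_es"] for p, k in zip(pi, ki)])

    time, event, event_lc = _survival_outcomes(true_es, spec, rng)
    frame = pd.DataFrame({
        "id": [f"s{i:06d}" for i in range(spec.n_subjects)],
        "time_days": time,
        "event_all_cause": event,
        "event_lung_cancer": event_lc,
        "weight": 1.0,
        "kernel": [kernels[k] for k in ki],
        "origES": orig_es,
        "normES": norm_es,
    })
    cohort, true_es = _case_control(frame, true_es, spec, rng)

    fixture = EndToEndFixture(phantom_scores=scores, profile=profile,
                              cohort=cohort, true_es=true_es, seed=seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(outdir / "phantom_scores.csv", index=False)
        profile.to_json(outdir / "reference_profile.json")
        cohort.to_csv(outdir / "cohort.csv")
        manifest = {
            "seed": seed,
            "n_phantoms": n_phantoms,
            "n_subjects": spec.n_subjects,
            "cohort_spec": {k: v for k, v in asdict(spec).items() if k != "kernel_noise"},
            "files": ["phantom_scores.csv", "reference_profile.json", "cohort.csv"],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return fixture
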