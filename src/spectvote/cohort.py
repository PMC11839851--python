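"""Synthetic DAT-SPECT slab cohorts with a simulated three-reader panel.

The generator emulates the structure of a clinical development dataset for
binary DAT-SPECT classification:

* a latent severity s in [0, 1] per scan (0 = fully normal striatal signal,
  1 = maximal Parkinson-typical reduction), drawn from a bimodal mixture of
  two Beta components plus a thin uniform "boundary band" around the class
  boundary — class overlap, not annotation noise, is the source of label
  uncertainty;
* 2D slab phantoms: two comma-shaped striatal regions (caudate + putamen
  per hemisphere) on a uniform elliptic background, with putaminal signal
  declining before caudate signal as severity rises;
* 12 augmentation instances per scan: 2 reconstruction variants (with and
  without attenuation/scatter correction) x 6 Gaussian smoothing levels
  (0, 10, 12, 14, 16, 18 mm FWHM);
* a panel of R = 3 simulated readers who vote "reduced" iff severity plus
  bounded perceptual noise exceeds their threshold, calibrated so that the
  four vote patterns occur at rates 46.1 / 2.0 / 2.8 / 49.1 % (95.2 %
  unanimity);
* out-of-distribution variants that shift resolution, contrast, noise and
  class prevalence (one instance per scan, a single reference label).

Everything is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

#: the six augmentation smoothing levels; 0 denotes the unsmoothed instance
SMOOTHING_LEVELS_MM: tuple[float, ...] = (0.0, 10.0, 12.0, 14.0, 16.0, 18.0)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class Variant(str, enum.Enum):
    """Reconstruction variant: with / without attenuation & scatter correction."""

    ASC = "ASC"
    NOASC = "NOASC"


class OODProfile(str, enum.Enum):
    IN_DIST = "IN_DIST"
    PPMI_LIKE = "PPMI_LIKE"  # slightly lower resolution, PD-enriched prevalence
    MPH_LIKE = "MPH_LIKE"  # higher resolution/contrast, less noise


# ---------------------------------------------------------------------
# phantom


@dataclass(frozen=True)
class PhantomParams:
    """Rendering parameters for one slab phantom.

    severity: 0 = normal striatal signal, 1 = maximal reduction.
    asymmetry: left/right putaminal imbalance (0 = symmetric).
    striatal_contrast_normal: striatum-to-background intensity ratio at
        severity 0; must exceed 1.
    intrinsic_fwhm_mm: scanner point-spread blur applied to every rendered
        image before the augmentation smoothing (0 disables it).
    """

    severity: float
    asymmetry: float = 0.3
    background_level: float = 10.0
    striatal_contrast_normal: float = 4.0
    noise_sd: float = 0.6
    pixel_size_mm: float = 3.0
    grid_size: int = 64
    intrinsic_fwhm_mm: float = 8.0

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")
        if self.striatal_contrast_normal <= 1.0:
            raise ValueError("striatal_contrast_normal must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must be in [0, 1]")


@dataclass
class SlabImage:
    pixels: np.ndarray
    variant: Variant
    smoothing_fwhm_mm: float
    scan_id: str

    def __post_init__(self):
        if self.smoothing_fwhm_mm not in SMOOTHING_LEVELS_MM:
            raise ValueError(
                f"smoothing FWHM {self.smoothing_fwhm_mm} not in {SMOOTHING_LEVELS_MM}"
            )
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be finite and non-negative")


def _mm_grid(grid_size: int, pixel_size_mm: float) -> tuple[np.ndarray, np.ndarray]:
    half = grid_size / 2.0 - 0.5
    coords = (np.arange(grid_size) - half) * pixel_size_mm
    return np.meshgrid(coords, coords, indexing="ij")  # (y, x) in mm


def _ellipse(y, x, cy, cx, ry, rx, angle_deg=0.0) -> np.ndarray:
    """Hard-edged rotated ellipse mask (mm coordinates)."""
    t = np.deg2rad(angle_deg)
    yr = (y - cy) * np.cos(t) - (x - cx) * np.sin(t)
    xr = (y - cy) * np.sin(t) + (x - cx) * np.cos(t)
    return (yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0


def brain_mask(grid_size: int = 64, pixel_size_mm: float = 3.0) -> np.ndarray:
    y, x = _mm_grid(grid_size, pixel_size_mm)
    return _ellipse(y, x, 0.0, 0.0, 88.0, 72.0)


def _striatal_parts(grid_size: int, pixel_size_mm: float) -> dict[str, np.ndarray]:
    """Caudate and putamen masks per hemisphere (left = negative x)."""
    y, x = _mm_grid(grid_size, pixel_size_mm)
    parts = {}
    for side, sx in (("left", -1.0), ("right", 1.0)):
        # caudate head: anterior-medial compact blob
        parts[f"caudate_{side}"] = _ellipse(y, x, -24.0, sx * 13.0, 12.0, 8.0)
        # putamen: elongated lateral structure sweeping posteriorly
        parts[f"putamen_{side}"] = _ellipse(
            y, x, -2.0, sx * 26.0, 21.0, 9.0, angle_deg=sx * 20.0
        )
    return parts


def striatal_mask(grid_size: int = 64, pixel_size_mm: float = 3.0) -> np.ndarray:
    parts = _striatal_parts(grid_size, pixel_size_mm)
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    for m in parts.values():
        mask |= m
    return mask


def background_roi_mask(grid_size: int = 64, pixel_size_mm: float = 3.0) -> np.ndarray:
    """Reference region: brain tissue away from the striatum (for DVR-style
    intensity normalization and contrast measurement)."""
    y, x = _mm_grid(grid_size, pixel_size_mm)
    inner = _ellipse(y, x, 0.0, 0.0, 76.0, 62.0)
    # generous margin around the striatum so smoothing spill-over is small
    margin = _ellipse(y, x, -12.0, 0.0, 48.0, 48.0)
    return inner & ~margin


def _signal_factors(severity: float, asymmetry: float) -> dict[str, float]:
    """Relative DAT signal per striatal part; putamen declines before caudate."""
    s_left = min(1.0, severity * (1.0 + 0.5 * asymmetry))
    s_right = max(0.0, severity * (1.0 - 0.5 * asymmetry))
    out = {}
    for side, s in (("left", s_left), ("right", s_right)):
        out[f"putamen_{side}"] = float(np.clip(1.0 - 1.6 * s, 0.0, 1.0))
        out[f"caudate_{side}"] = float(1.0 - 0.85 * s * s)
    return out


#: NOASC reconstruction: brighter background, flatter contrast
NOASC_BACKGROUND_GAIN = 1.25
NOASC_CONTRAST_GAIN = 0.75


def render_template(params: PhantomParams, variant: Variant = Variant.ASC) -> np.ndarray:
    """Noise-free, convolution-free intensity template."""
    g, px = params.grid_size, params.pixel_size_mm
    bg_level = params.background_level
    contrast = params.striatal_contrast_normal
    if variant is Variant.NOASC:
        bg_level *= NOASC_BACKGROUND_GAIN
        contrast = 1.0 + (contrast - 1.0) * NOASC_CONTRAST_GAIN
    img = np.zeros((g, g), dtype=np.float64)
    img[brain_mask(g, px)] = bg_level
    factors = _signal_factors(params.severity, params.asymmetry)
    for name, mask in _striatal_parts(g, px).items():
        img[mask] = bg_level * (1.0 + (contrast - 1.0) * factors[name])
    return img


def generate_phantom(
    params: PhantomParams,
    variant: Variant | str,
    smoothing_fwhm_mm: float,
    seed: int,
    scan_id: str = "scan",
) -> SlabImage:
    """Render one slab instance: template + noise + PSF + augmentation smoothing.

    Deterministic for a fixed (params, variant, fwhm, seed).  Noise is added
    before any smoothing, so heavier smoothing levels have visibly lower
    noise, as in reconstructed emission images.
    """
    variant = Variant(variant)
    if smoothing_fwhm_mm not in SMOOTHING_LEVELS_MM:
        raise ValueError(
            f"smoothing FWHM {smoothing_fwhm_mm} not in {SMOOTHING_LEVELS_MM}"
        )
    img = render_template(params, variant)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    total_fwhm = float(np.hypot(params.intrinsic_fwhm_mm, smoothing_fwhm_mm))
    if total_fwhm > 0:
        sigma_px = total_fwhm * FWHM_TO_SIGMA / params.pixel_size_mm
        img = gaussian_filter(img, sigma_px, mode="constant")
    img = np.clip(img, 0.0, None)
    return SlabImage(img, variant, smoothing_fwhm_mm, scan_id)


# ---------------------------------------------------------------------
# readers


@dataclass(frozen=True)
class ReaderModel:
    """Each reader votes "reduced" iff severity + noise exceeds a threshold.

    Perceptual noise is uniform with the given standard deviation, hence
    bounded by sqrt(3) * sd: scans farther than that from every threshold
    are always voted unanimously.
    """

    thresholds: tuple[float, ...] = (0.5, 0.5, 0.5)
    noise_sds: tuple[float, ...] = (0.03, 0.03, 0.03)

    def __post_init__(self):
        if len(self.thresholds) < 1 or len(self.thresholds) != len(self.noise_sds):
            raise ValueError("need one threshold and one noise sd per reader")
        if any(sd < 0 for sd in self.noise_sds):
            raise ValueError("noise sds must be >= 0")

    @property
    def n_readers(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class ReaderVotes:
    """Ordered binary votes (0 = normal, 1 = reduced)."""

    votes: tuple[int, ...]

    def __post_init__(self):
        if len(self.votes) == 0:
            raise ValueError("empty vote tuple")
        if any(v not in (0, 1) for v in self.votes):
            raise ValueError("votes must be 0 or 1")

    @property
    def unanimous(self) -> bool:
        return len(set(self.votes)) == 1

    def __iter__(self):
        return iter(self.votes)

    def __len__(self):
        return len(self.votes)


def simulate_readers(severity: float, model: ReaderModel, seed: int) -> ReaderVotes:
    rng = np.random.default_rng(seed)
    votes = []
    for theta, sd in zip(model.thresholds, model.noise_sds):
        half_width = np.sqrt(3.0) * sd
        noise = rng.uniform(-half_width, half_width) if sd > 0 else 0.0
        votes.append(int(severity + noise > theta))
    return ReaderVotes(tuple(votes))


# ---------------------------------------------------------------------
# severity mixture


@dataclass(frozen=True)
class SeverityMixture:
    """Bimodal severity distribution with a thin uniform boundary band.

    Defaults are calibrated (jointly with :class:`ReaderModel`) so that the
    simulated three-reader panel reproduces the target vote-pattern rates
    46.1 / 2.0 / 2.8 / 49.1 % (unanimity 95.2 %).
    """

    band_mass: float = 0.0764
    band_center: float = 0.4882
    band_width: float = 0.06
    reduced_mass: float = 0.4917  # among non-band scans
    beta_a: float = 2.0
    beta_b: float = 4.0
    normal_hi: float = 0.44  # normal component support [0, normal_hi]
    reduced_lo: float = 0.56  # reduced component support [reduced_lo, 1]

    def sample(self, rng: np.random.Generator) -> float:
        u = rng.random()
        if u < self.band_mass:
            return float(
                self.band_center + self.band_width * (rng.random() - 0.5)
            )
        if rng.random() < self.reduced_mass:
            return float(
                self.reduced_lo + (1.0 - self.reduced_lo) * rng.beta(self.beta_a, self.beta_b)
            )
        return float(self.normal_hi * rng.beta(self.beta_a, self.beta_b))


#: class boundary on the latent severity scale
SEVERITY_BOUNDARY = 0.5


# ---------------------------------------------------------------------
# cohort


@dataclass
class ScanRecord:
    scan_id: str
    severity: float
    true_class: int
    instances: list[SlabImage]
    votes: ReaderVotes


@dataclass(frozen=True)
class CohortConfig:
    n_scans: int = 200
    seed: int = 0
    mixture: SeverityMixture = field(default_factory=SeverityMixture)
    reader_model: ReaderModel = field(default_factory=ReaderModel)
    target_unanimity: float = 0.952
    ood_profile: OODProfile = OODProfile.IN_DIST
    phantom: PhantomParams = field(default_factory=lambda: PhantomParams(severity=0.0))

    def __post_init__(self):
        if self.n_scans < 10:
            raise ValueError("n_scans must be >= 10")
        if not 0.0 < self.target_unanimity <= 1.0:
            raise ValueError("target_unanimity must be in (0, 1]")


#: out-of-distribution acquisition shifts relative to the development profile
OOD_SHIFTS = {
    # slightly lower spatial resolution, research-cohort prevalence
    OODProfile.PPMI_LIKE: dict(
        intrinsic_fwhm_mm=11.0, contrast_gain=1.0, noise_gain=1.1, prevalence=0.679
    ),
    # markedly better resolution -> higher contrast, less noise
    OODProfile.MPH_LIKE: dict(
        intrinsic_fwhm_mm=5.0, contrast_gain=1.5, noise_gain=0.5, prevalence=0.511
    ),
}


def _scan_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def generate_cohort(config: CohortConfig) -> list[ScanRecord]:
    """In-distribution cohort: 12 instances per scan + three reader votes."""
    if config.ood_profile is not OODProfile.IN_DIST:
        raise ValueError("use generate_ood_cohort for OOD profiles")
    records = []
    for i, ss in enumerate(_scan_seeds(config.seed, config.n_scans)):
        sev_ss, vote_ss, asc_ss, noasc_ss = ss.spawn(4)
        severity = config.mixture.sample(np.random.default_rng(sev_ss))
        votes = simulate_readers(
            severity, config.reader_model, int(vote_ss.generate_state(1)[0])
        )
        params = replace(config.phantom, severity=severity)
        scan_id = f"scan{i:05d}"
        instances = []
        for variant, noise_ss in ((Variant.ASC, asc_ss), (Variant.NOASC, noasc_ss)):
            noise_seed = int(noise_ss.generate_state(1)[0])
            for fwhm in SMOOTHING_LEVELS_MM:
                instances.append(
                    generate_phantom(params, variant, fwhm, noise_seed, scan_id)
                )
        records.append(
            ScanRecord(
                scan_id=scan_id,
                severity=severity,
                true_class=int(severity > SEVERITY_BOUNDARY),
                instances=instances,
                votes=votes,
            )
        )
    return records


def generate_ood_cohort(config: CohortConfig) -> list[ScanRecord]:
    """Out-of-distribution test cohort: one instance and one label per scan."""
    if config.ood_profile is OODProfile.IN_DIST:
        raise ValueError("generate_ood_cohort requires PPMI_LIKE or MPH_LIKE")
    shift = OOD_SHIFTS[config.ood_profile]
    mixture = replace(
        config.mixture,
        reduced_mass=float(
            (shift["prevalence"] - config.mixture.band_mass * _band_above_boundary(config.mixture))
            / (1.0 - config.mixture.band_mass)
        ),
    )
    records = []
    for i, ss in enumerate(_scan_seeds(config.seed, config.n_scans)):
        sev_ss, _vote_ss, img_ss, _ = ss.spawn(4)
        severity = mixture.sample(np.random.default_rng(sev_ss))
        params = replace(
            config.phantom,
            severity=severity,
            intrinsic_fwhm_mm=shift["intrinsic_fwhm_mm"],
            striatal_contrast_normal=1.0
            + (config.phantom.striatal_contrast_normal - 1.0) * shift["contrast_gain"],
            noise_sd=config.phantom.noise_sd * shift["noise_gain"],
        )
        scan_id = f"{config.ood_profile.value.lower()}{i:05d}"
        image = generate_phantom(
            params, Variant.ASC, 0.0, int(img_ss.generate_state(1)[0]), scan_id
        )
        label = int(severity > SEVERITY_BOUNDARY)
        records.append(
            ScanRecord(
                scan_id=scan_id,
                severity=severity,
                true_class=label,
                instances=[image],
                votes=ReaderVotes((label,)),
            )
        )
    return records


def _band_above_boundary(mixture: SeverityMixture) -> float:
    """Fraction of the boundary band above the class boundary."""
    lo = mixture.band_center - mixture.band_width / 2.0
    hi = mixture.band_center + mixture.band_width / 2.0
    if hi <= SEVERITY_BOUNDARY:
        return 0.0
    return min(1.0, (hi - SEVERITY_BOUNDARY) / mixture.band_width)


# ---------------------------------------------------------------------
# tabular views / persistence


def votes_table(records: list[ScanRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"scan_id": rec.scan_id}
        for r, v in enumerate(rec.votes, start=1):
            row[f"reader_{r}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_table(records: list[ScanRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for k, inst in enumerate(rec.instances):
            rows.append(
                {
                    "scan_id": rec.scan_id,
                    "instance": k,
                    "severity": rec.severity,
                    "true_class": rec.true_class,
                    "variant": inst.variant.value,
                    "smoothing_fwhm_mm": inst.smoothing_fwhm_mm,
                }
            )
    return pd.DataFrame(rows)


def save_cohort(records: list[ScanRecord], prefix) -> None:
    """Write pixels to an .npz archive plus sidecar and votes CSVs."""
    import pathlib

    prefix = pathlib.Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for rec in records:
        for k, inst in enumerate(rec.instances):
            arrays[f"{rec.scan_id}_{k}"] = inst.pixels.astype(np.float32)
    np.savez_compressed(str(prefix) + "_images.npz", **arrays)
    cohort_table(records).to_csv(str(prefix) + "_instances.csv", index=False)
    votes_table(records).to_csv(str(prefix) + "_votes.csv", index=False)


def load_cohort(prefix) -> list[ScanRecord]:
    """Inverse of :func:`save_cohort`."""
    import pathlib

    prefix = pathlib.Path(prefix)
    arrays = np.load(str(prefix) + "_images.npz")
    instances_df = pd.read_csv(str(prefix) + "_instances.csv")
    votes_df = pd.read_csv(str(prefix) + "_votes.csv").set_index("scan_id")
    reader_cols = [c for c in votes_df.columns if c.startswith("reader_")]
    records = []
    for scan_id, g in instances_df.groupby("scan_id", sort=True):
        g = g.sort_values("instance")
        instances = [
            SlabImage(
                arrays[f"{scan_id}_{int(row.instance)}"].astype(np.float64),
                Variant(row.variant),
                float(row.smoothing_fwhm_mm),
                scan_id,
            )
            for row in g.itertuples()
        ]
        votes = ReaderVotes(tuple(int(votes_df.loc[scan_id, c]) for c in reader_cols))
        records.append(
            ScanRecord(
                scan_id=scan_id,
                severity=float(g.severity.iloc[0]),
                true_class=int(g.true_class.iloc[0]),
                instances=instances,
                votes=votes,
            )
        )
    return records


def export_nifti(records: list[ScanRecord], out_dir, pixel_size_mm: float = 3.0) -> list[str]:
    """One NIfTI file per instance (pixel size recorded in the affine)."""
    import pathlib

    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])
    paths = []
    for rec in records:
        for k, inst in enumerate(rec.instances):
            path = out / f"{rec.scan_id}_{k:02d}_{inst.variant.value}_{int(inst.smoothing_fwhm_mm)}mm.nii.gz"
            nib.save(nib.Nifti1Image(inst.pixels[..., None].astype(np.float32), affine), path)
            paths.append(str(path))
    return paths
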