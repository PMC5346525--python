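"""Synthetic two-group cohort with known ground truth.

Generates everything the analysis pipeline consumes, with the truth recorded
in a manifest so every downstream stage is testable by parameter recovery:

* ROI time series: exact fractional Gaussian noise (circulant-embedding /
  Davies-Harte construction) per region, mixed through a block (community)
  correlation structure with configurable within/between-block levels.
* Gray-matter volumes: a smooth shared template field plus parcel-level group
  effects and smooth subject noise, clipped to [0, 1], with an integer
  parcellation volume (label 0 = background border).
* Cognitive scores: per-group multivariate normal draws at configurable
  means/SDs with a uniform inter-test correlation, plus a minority-status
  Bernoulli covariate and a distress (CAD) score per group.

A latent per-patient factor ``u`` couples the functional and structural
generative parameters: it raises the within-block functional correlation
(raising functional clustering) while amplifying the gray-matter template
fluctuation (lowering structural similarity-network clustering), injecting
the negative structure-function topology coupling in the patient group only;
``fc_coupling = sc_coupling = 0`` switches the injection off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .functional import RoiTimeSeries
from .structural import GrayMatterMap

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "COGNITIVE_MOMENTS",
    "PERFORMANCE_MEASURES",
    "SELF_REPORT_MEASURES",
    "simulate_fgn",
    "fgn_autocovariance",
    "simulate_roi_timeseries",
    "simulate_gray_matter_cohort",
    "simulate_cognitive_scores",
    "simulate_latents",
]

#: per-test (patient, control) x (mean, SD); the cognitive study conditions
COGNITIVE_MOMENTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "ravlt_total": ((52.5, 8.6), (56.1, 7.6)),
    "ravlt_interference": ((5.82, 1.8), (6.76, 1.8)),
    "ravlt_delayed": ((10.9, 2.7), (11.6, 2.2)),
    "ctmt1": ((50.7, 7.3), (55.5, 9.7)),
    "ctmt2": ((52.7, 10.6), (54.2, 10.4)),
    "ctmt3": ((50.1, 8.2), (50.1, 10.1)),
    "ctmt4": ((54.8, 10.1), (56.5, 10.1)),
    "ctmt5": ((50.6, 8.8), (54.0, 9.5)),
    "cowa": ((42.5, 13.0), (49.5, 12.8)),
    "brief_gec": ((51.3, 9.2), (45.3, 9.8)),
    "prmq": ((36.7, 8.8), (32.8, 8.2)),
}

PERFORMANCE_MEASURES = [
    "ravlt_total", "ravlt_interference", "ravlt_delayed",
    "ctmt1", "ctmt2", "ctmt3", "ctmt4", "ctmt5", "cowa",
]
SELF_REPORT_MEASURES = ["brief_gec", "prmq"]

# deterministic sub-stream ids for SeedSequence spawning
_STREAM_TS, _STREAM_GM, _STREAM_COG, _STREAM_LATENT = 0, 1, 2, 3


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the study design at desk scale: 30 + 30 subjects, 90
    regions, 216 volumes, group-mean Hurst exponents 0.19 (patients) versus
    0.22 (controls), block community structure with within/between-block
    correlations 0.6/0.1, and cognitive group moments from the study tables.
    """

    n_patients: int = 30
    n_controls: int = 30
    n_regions: int = 90
    n_volumes: int = 216
    hurst_patients: float = 0.19
    hurst_controls: float = 0.22
    n_blocks: int = 6
    within_block_r: float = 0.6
    between_block_r: float = 0.1
    #: latent-u slope on patients' within-block correlation
    fc_coupling: float = 0.18
    #: latent-u slope on patients' log template-fluctuation amplitude
    sc_coupling: float = 0.8
    gm_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    gm_smooth_vox: float = 2.0
    gm_base_level: float = 0.55
    gm_fluct_sd: float = 0.12
    gm_noise_sd: float = 0.05
    #: per-parcel additive mean shift applied to patients (parcel id -> shift)
    gm_group_effect: dict[int, float] = field(default_factory=dict)
    #: parcel count of the synthetic atlas; None -> one parcel per region
    n_parcels: int | None = None
    cognitive_moments: dict = field(default_factory=lambda: dict(COGNITIVE_MOMENTS))
    cognitive_corr: float = 0.3
    minority_rate: tuple[float, float] = (0.33, 0.20)
    cad_moments: tuple[tuple[float, float], tuple[float, float]] = (
        (52.0, 9.8),
        (43.7, 9.6),
    )
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels is None:
            self.n_parcels = self.n_regions
        for name in ("n_patients", "n_controls", "n_regions", "n_volumes", "n_blocks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for h in (self.hurst_patients, self.hurst_controls):
            if not 0 < h < 1:
                raise ValueError("Hurst exponents must lie in (0, 1)")
        for r in (self.within_block_r, self.between_block_r):
            if not -1 <= r <= 1:
                raise ValueError("correlation levels must lie in [-1, 1]")
        if not 0 <= self.between_block_r <= self.within_block_r < 1:
            raise ValueError(
                "need 0 <= between_block_r <= within_block_r < 1 for a PSD block model"
            )
        for moments in self.cognitive_moments.values():
            if moments[0][1] <= 0 or moments[1][1] <= 0:
                raise ValueError("cognitive SDs must be positive")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def subject_ids(self) -> list[str]:
        return [f"sub-{i:03d}" for i in range(self.n_subjects)]

    def groups(self) -> list[str]:
        return ["patient"] * self.n_patients + ["control"] * self.n_controls

    def community_blocks(self) -> list[list[int]]:
        """Contiguous near-equal partition of regions into ``n_blocks``."""
        bounds = np.linspace(0, self.n_regions, self.n_blocks + 1).astype(int)
        blocks = [list(range(bounds[k], bounds[k + 1])) for k in range(self.n_blocks)]
        if sorted(r for b in blocks for r in b) != list(range(self.n_regions)):
            raise ValueError("block partition must cover all regions exactly once")
        return blocks

    def region_labels(self) -> list[str]:
        return [f"ROI_{i + 1:02d}" for i in range(self.n_regions)]

    def to_json(self) -> str:
        d = asdict(self)
        d["gm_shape"] = list(d["gm_shape"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["gm_shape"] = tuple(d["gm_shape"])
        d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        d["minority_rate"] = tuple(d["minority_rate"])
        d["cad_moments"] = tuple(tuple(x) for x in d["cad_moments"])
        d["cognitive_moments"] = {
            k: (tuple(v[0]), tuple(v[1])) for k, v in d["cognitive_moments"].items()
        }
        d["gm_group_effect"] = {int(k): v for k, v in d["gm_group_effect"].items()}
        return cls(**d)


@dataclass
class TruthManifest:
    """Ground truth written alongside every simulated cohort.

    Reproducible byte-for-byte from (config, seed).  The Hurst truth uses the
    study's group means directly; note those published values are group
    summaries whose SD mixes subject and estimation variance, so the per-group
    truth here is a single H shared by all regions of a group.
    """

    seed: int
    config_json: str
    true_hurst: dict[str, list[float]]
    latent_u: dict[str, float]
    cognitive_means: dict[str, dict[str, float]]
    blocks: list[list[int]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise."""
    k = np.abs(lags).astype(float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def simulate_fgn(length: int, hurst: float, seed) -> np.ndarray:
    """Exact stationary fGn via circulant embedding (Davies-Harte).

    ``seed`` may be an int, a SeedSequence, or a Generator.  Raises when the
    circulant embedding is not positive semidefinite (extreme H with short
    length), rather than falling back to an approximation.
    """
    if length < 16:
        raise ValueError("length must be >= 16")
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = length
    gamma = fgn_autocovariance(hurst, np.arange(n + 1))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant row, length 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise ValueError(
            f"circulant embedding not positive semidefinite for H={hurst}, "
            f"length={length}; increase the length"
        )
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    a = np.zeros(m, dtype=complex)
    a[0] = np.sqrt(lam[0]) * rng.standard_normal()
    a[n] = np.sqrt(lam[n]) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    w = rng.standard_normal(n - 1)
    a[1:n] = np.sqrt(lam[1:n] / 2.0) * (u + 1j * w)
    a[n + 1 :] = np.conj(a[n - 1 : 0 : -1])
    x = np.fft.fft(a) / np.sqrt(m)
    return np.ascontiguousarray(x.real[:n])


def simulate_latents(config: SimulationConfig) -> np.ndarray:
    """Per-subject standard-normal latent u (used for coupling in patients)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAM_LATENT,))
    )
    return rng.standard_normal(config.n_subjects)


def _subject_params(config: SimulationConfig, subject_index: int, latents: np.ndarray):
    is_patient = subject_index < config.n_patients
    h = config.hurst_patients if is_patient else config.hurst_controls
    u = latents[subject_index]
    r_w = config.within_block_r
    fluct_scale = 1.0
    if is_patient:
        r_w = float(
            np.clip(r_w + config.fc_coupling * u, config.between_block_r + 0.02, 0.95)
        )
        fluct_scale = float(np.exp(config.sc_coupling * u))
    return is_patient, h, r_w, fluct_scale, u


def simulate_roi_timeseries(
    config: SimulationConfig, subject_index: int, latents: np.ndarray | None = None
) -> RoiTimeSeries:
    """One subject's region-by-time matrix with block community structure.

    Each region's signal is a weighted sum of a subject-global fGn factor, a
    block-shared fGn factor and an idiosyncratic fGn, all at the subject's
    true H, with weights ``a^2 = r_between``, ``a^2 + b^2 = r_within`` so the
    expected correlations hit the configured levels exactly.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError("subject_index out of range")
    if latents is None:
        latents = simulate_latents(config)
    _, h, r_w, _, _ = _subject_params(config, subject_index, latents)
    blocks = config.community_blocks()
    a2 = config.between_block_r
    b2 = r_w - a2
    c2 = 1.0 - r_w
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(_STREAM_TS, subject_index)
    )
    rng = np.random.default_rng(ss)
    t = config.n_volumes
    g = simulate_fgn(t, h, rng)
    block_factors = np.stack([simulate_fgn(t, h, rng) for _ in blocks])
    data = np.empty((config.n_regions, t))
    for k, block in enumerate(blocks):
        for r in block:
            e = simulate_fgn(t, h, rng)
            data[r] = np.sqrt(a2) * g + np.sqrt(b2) * block_factors[k] + np.sqrt(c2) * e
    return RoiTimeSeries(
        subject_id=config.subject_ids()[subject_index],
        data=data,
        region_labels=config.region_labels(),
        tr_seconds=config.tr_seconds,
    )


def _parcel_splits(n_parcels: int) -> tuple[int, int, int]:
    """Balanced three-factor decomposition of the parcel count."""
    best = None
    for a in range(1, int(n_parcels ** (1 / 3)) + 2):
        if n_parcels % a:
            continue
        rest = n_parcels // a
        for b in range(a, int(rest**0.5) + 1):
            if rest % b:
                continue
            c = rest // b
            spread = c - a
            if best is None or spread < best[0]:
                best = (spread, (a, c, b))
    if best is None:
        raise ValueError(f"cannot factor {n_parcels} into a 3-axis parcel grid")
    return best[1]


def make_parcellation(config: SimulationConfig) -> np.ndarray:
    """Integer label volume: border = 0 (background), interior split into
    ``n_parcels`` near-equal boxes labeled 1..n_parcels."""
    shape = config.gm_shape
    labels = np.zeros(shape, dtype=np.int32)
    splits = _parcel_splits(config.n_parcels)
    edges = [
        np.linspace(1, s - 1, k + 1).astype(int) for s, k in zip(shape, splits)
    ]
    lab = 1
    for i in range(splits[0]):
        for j in range(splits[1]):
            for k in range(splits[2]):
                labels[
                    edges[0][i] : edges[0][i + 1],
                    edges[1][j] : edges[1][j + 1],
                    edges[2][k] : edges[2][k + 1],
                ] = lab
                lab += 1
    return labels


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    field_ -= field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def simulate_gray_matter_cohort(
    config: SimulationConfig, latents: np.ndarray | None = None
) -> tuple[list[GrayMatterMap], np.ndarray]:
    """Smooth template + parcel group effect + smooth subject noise, per subject.

    Patient volumes scale the template's zero-mean fluctuation by a subject
    factor exp(sc_coupling * u): stronger fluctuation pushes densities into
    the [0, 1] clipping range and past the cube-inclusion rule, which lowers
    the similarity network's clustering, so the latent u couples structural
    topology (down) and functional topology (up) in opposite directions.  A
    one-voxel border is background (mask off, label 0).
    """
    shape = config.gm_shape
    n_cubes = (shape[0] // 3) * (shape[1] // 3) * (shape[2] // 3)
    if n_cubes < 200:
        raise ValueError(f"grid {shape} holds only {n_cubes} cubes; need >= 200")
    if latents is None:
        latents = simulate_latents(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAM_GM,))
    )
    template_fluct = _smooth_field(rng, shape, config.gm_smooth_vox) * config.gm_fluct_sd
    parcellation = make_parcellation(config)
    mask = parcellation > 0
    effect = np.zeros(shape)
    for parcel, shift in config.gm_group_effect.items():
        effect[parcellation == parcel] = shift
    maps = []
    for i in range(config.n_subjects):
        is_patient, _, _, fluct_scale, _ = _subject_params(config, i, latents)
        noise = (
            _smooth_field(rng, shape, config.gm_smooth_vox) * config.gm_noise_sd
            if config.gm_noise_sd > 0
            else np.zeros(shape)
        )
        vol = config.gm_base_level + fluct_scale * template_fluct + noise
        if is_patient:
            vol = vol + effect
        vol = np.clip(vol, 0.0, 1.0)
        vol[~mask] = 0.0
        maps.append(
            GrayMatterMap(
                subject_id=config.subject_ids()[i],
                volume=vol,
                voxel_size_mm=config.voxel_size_mm,
                mask=mask.copy(),
            )
        )
    return maps, parcellation


def simulate_cognitive_scores(
    config: SimulationConfig, latents: np.ndarray | None = None
) -> pd.DataFrame:
    """Cohort covariates and cognitive scores.

    Scores are drawn per group from a multivariate normal with the configured
    means/SDs and uniform inter-test correlation; minority status is Bernoulli
    per group and the distress (CAD) score normal per group.
    """
    tests = list(config.cognitive_moments)
    k = len(tests)
    corr = np.full((k, k), config.cognitive_corr)
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("inter-test correlation matrix is not positive semidefinite")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAM_COG,))
    )
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    rows = []
    groups = config.groups()
    ids = config.subject_ids()
    for gi, (group, n) in enumerate(
        [("patient", config.n_patients), ("control", config.n_controls)]
    ):
        means = np.array([config.cognitive_moments[t][gi][0] for t in tests])
        sds = np.array([config.cognitive_moments[t][gi][1] for t in tests])
        z = rng.standard_normal((n, k)) @ chol.T
        scores = means + sds * z
        minority = (rng.random(n) < config.minority_rate[gi]).astype(int)
        cad = config.cad_moments[gi][0] + config.cad_moments[gi][1] * rng.standard_normal(n)
        offset = 0 if group == "patient" else config.n_patients
        for j in range(n):
            row = {
                "subject_id": ids[offset + j],
                "group": group,
                "minority": int(minority[j]),
                "cad_score": float(cad[j]),
            }
            row.update({t: float(scores[j, m]) for m, t in enumerate(tests)})
            rows.append(row)
    assert [r["group"] for r in rows] == groups
    return pd.DataFrame(rows)


def build_truth_manifest(
    config: SimulationConfig, latents: np.ndarray | None = None
) -> TruthManifest:
    if latents is None:
        latents = simulate_latents(config)
    ids = config.subject_ids()
    true_h = {}
    for i, sid in enumerate(ids):
        h = config.hurst_patients if i < config.n_patients else config.hurst_controls
        true_h[sid] = [h] * config.n_regions
    tests = list(config.cognitive_moments)
    cog_means = {
        "patient": {t: config.cognitive_moments[t][0][0] for t in tests},
        "control": {t: config.cognitive_moments[t][1][0] for t in tests},
    }
    return TruthManifest(
        seed=config.seed,
        config_json=config.to_json(),
        true_hurst=true_h,
        latent_u={sid: float(latents[i]) for i, sid in enumerate(ids)},
        cognitive_means=cog_means,
        blocks=config.community_blocks(),
    )
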