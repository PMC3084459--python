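"""Synthetic multi-run fMRI datasets with known ground truth.

Emulates a virtual-reality decoding experiment: several runs of 4D volumes
in which gray-matter-confined activation blobs track HRF-convolved rating
time courses, on top of a smooth positive baseline, run-specific
low-frequency scanner drift (cosine mixtures below 0.0015 Hz), and iid
Gaussian noise.  Every component (weight maps, raw and convolved ratings,
drift, noise) is available as ground truth, so each downstream stage —
masking, detrending, kernel regression, deconvolution, match filtering —
can be validated by parameter recovery instead of real data.

Randomness is split into independent named streams (baseline/mask, weights,
ratings, drift, noise), so changing one amplitude never perturbs the other
components: the injected signal is exactly linear in ``effect_amplitude``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .hrf import canonical_hrf, convolution_matrix
from .preprocess import MaskVolume

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_rating", "generate_dataset"]

_RATING_KINDS = ("block", "spikes", "continuous")

# stream labels -> offset added to the spawned seed sequence
_STREAMS = ("baseline", "weights", "ratings", "drift", "noise")


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic dataset.

    Desk-scale defaults (16 x 16 x 8 grid, 128 scans/run) keep tests fast;
    :meth:`full_scale` returns the full-scale design (64 x 64 x 34 voxels, 3 runs
    of 704 scans at TR = 1.75 s).
    """

    grid_dims: tuple[int, int, int] = (16, 16, 8)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_runs: int = 3
    scans_per_run: int = 128
    tr_seconds: float = 1.75
    n_ratings: int = 3
    rating_kinds: tuple[str, ...] = ("block", "spikes", "continuous")
    effect_amplitude: float = 1.0
    n_active_blobs: int = 3
    blob_sigma_vox: float = 1.5
    baseline_amplitude: float = 100.0
    drift_amplitude: float = 5.0
    drift_max_freq_hz: float = 0.0015
    noise_sd: float = 1.0
    gm_fraction: float = 0.3
    block_length: int = 10
    spike_count: int = 7
    signal_hrf_peak_delay_s: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid dimensions must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.n_runs < 1 or self.scans_per_run < 2:
            raise ValueError("need >= 1 run of >= 2 scans")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        for amp in (self.effect_amplitude, self.drift_amplitude, self.noise_sd):
            if amp < 0:
                raise ValueError("amplitudes and noise sd must be >= 0")
        if not (0 < self.drift_max_freq_hz < 1.0 / (2.0 * self.tr_seconds)):
            raise ValueError("drift_max_freq_hz must lie in (0, Nyquist)")
        if len(self.rating_kinds) != self.n_ratings:
            raise ValueError("rating_kinds must list one kind per rating")
        if any(k not in _RATING_KINDS for k in self.rating_kinds):
            raise ValueError(f"rating kinds must be drawn from {_RATING_KINDS}")

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationConfig":
        """Full-scale design: 64 x 64 x 34 grid, 3 runs x 704 scans, TR 1.75 s."""
        defaults = dict(grid_dims=(64, 64, 34), n_runs=3, scans_per_run=704)
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("grid_dims", "voxel_size_mm", "rating_kinds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_dims", "voxel_size_mm", "rating_kinds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Generated volumes plus every ground-truth component."""

    volumes: np.ndarray  # (nx, ny, nz, total_scans)
    gm_mask: MaskVolume
    true_weight_maps: list[np.ndarray]
    raw_ratings: list[np.ndarray]
    convolved_ratings: list[np.ndarray]
    run_boundaries: list[tuple[int, int]]
    rating_names: list[str]
    config: SimulationConfig

    @property
    def n_scans(self) -> int:
        return self.volumes.shape[3]


def _spike_raw_template(tr_seconds: float) -> np.ndarray:
    """Raw-rating event shape: HRF response to a 3-scan boxcar, peak = 1.

    The undershoot is clipped at zero (raw ratings live in [0, 1]) and the
    template trimmed to its positive support.
    """
    h = canonical_hrf(tr_seconds)
    box = np.zeros(h.samples.shape[0] + 3)
    box[:3] = 1.0
    resp = np.convolve(box, h.samples)[: box.shape[0]]
    resp = np.clip(resp / resp.max(), 0.0, None)
    keep = np.flatnonzero(resp > 1e-3)
    return resp[: keep[-1] + 1]


def generate_rating(
    kind: str,
    n_scans: int,
    params: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate one raw rating time course in [0, 1].

    kinds
    -----
    block : binary 0/1 in contiguous blocks of roughly ``block_length`` scans.
    spikes : ``k`` (default 7) non-overlapping copies of a fixed event
        template (the HRF response to a 3-scan boxcar) on a zero baseline.
    continuous : a smoothed random walk rescaled to [0, 1].
    """
    if n_scans < 2:
        raise ValueError("n_scans must be >= 2")
    if kind not in _RATING_KINDS:
        raise ValueError(f"unknown rating kind {kind!r}")
    params = dict(params or {})
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if kind == "block":
        block_length = int(params.get("block_length", 10))
        if block_length < 1:
            raise ValueError("block_length must be >= 1")
        if block_length >= n_scans:
            return np.ones(n_scans)  # degenerate: one block spans the run
        z = np.zeros(n_scans)
        pos = 0
        state = bool(rng.integers(0, 2))
        while pos < n_scans:
            span = int(rng.integers(max(1, block_length // 2), int(1.5 * block_length) + 1))
            if state:
                z[pos : pos + span] = 1.0
            pos += span
            state = not state
        return z

    if kind == "spikes":
        k = int(params.get("k", 7))
        template = params.get("template")
        if template is None:
            template = _spike_raw_template(float(params.get("tr_seconds", 1.75)))
        template = np.asarray(template, dtype=float)
        m = template.shape[0]
        # at least one zero scan between copies keeps the segments disjoint;
        # an end margin (default one template length) leaves room for the
        # evoked hemodynamic response to complete within the run
        margin = int(params.get("end_margin", m))
        free = n_scans - k * m - (k - 1) - margin
        if free < 0:
            raise ValueError(
                f"cannot fit {k} non-overlapping {m}-scan templates in {n_scans} scans"
            )
        # stars-and-bars: distribute the free scans into k+1 gaps
        cuts = np.sort(rng.integers(0, free + 1, size=k))
        onsets = cuts + np.arange(k) * (m + 1)
        z = np.zeros(n_scans)
        for onset in onsets:
            z[onset : onset + m] = template
        return z

    # continuous
    step = float(params.get("step_sd", 1.0))
    smooth = float(params.get("smooth_scans", 3.0))
    walk = np.cumsum(rng.normal(0.0, step, size=n_scans))
    walk = ndimage.gaussian_filter1d(walk, smooth, mode="nearest")
    lo, hi = walk.min(), walk.max()
    if hi - lo < 1e-12:
        return np.full(n_scans, 0.5)
    return (walk - lo) / (hi - lo)


def _smooth_field(rng: np.random.Generator, dims, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=dims), sigma, mode="nearest")
    return f


def _make_mask(rng: np.random.Generator, cfg: SimulationConfig) -> MaskVolume:
    field3d = _smooth_field(rng, cfg.grid_dims, sigma=2.0)
    thr = np.quantile(field3d, 1.0 - cfg.gm_fraction)
    mask = field3d > thr
    if not mask.any():
        raise ValueError("generated mask is empty")
    return MaskVolume(data=mask.astype(np.uint8), voxel_size_mm=cfg.voxel_size_mm)


def _make_weight_map(
    rng: np.random.Generator, cfg: SimulationConfig, mask: np.ndarray
) -> np.ndarray:
    coords = np.argwhere(mask)
    grids = np.meshgrid(*[np.arange(d) for d in cfg.grid_dims], indexing="ij")
    w = np.zeros(cfg.grid_dims)
    for _ in range(cfg.n_active_blobs):
        cx, cy, cz = coords[rng.integers(0, coords.shape[0])]
        d2 = (grids[0] - cx) ** 2 + (grids[1] - cy) ** 2 + (grids[2] - cz) ** 2
        blob = np.exp(-0.5 * d2 / cfg.blob_sigma_vox**2)
        blob[d2 > (3.0 * cfg.blob_sigma_vox) ** 2] = 0.0  # compact support
        w += blob
    w[~mask] = 0.0
    return w


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset from a :class:`SimulationConfig`.

    volumes = baseline + per-run drift + sum_r effect * weight_map_r *
    convolved_rating_r + iid Gaussian noise.  Bit-reproducible for a given
    config and seed.
    """
    cfg = config
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(_STREAMS, np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS)))
    }
    n_total = cfg.n_runs * cfg.scans_per_run
    run_boundaries = [
        (r * cfg.scans_per_run, (r + 1) * cfg.scans_per_run) for r in range(cfg.n_runs)
    ]

    # baseline: smooth positive field, constant over time
    base_rng = streams["baseline"]
    baseline = cfg.baseline_amplitude * (
        1.0 + 0.2 * _smooth_field(base_rng, cfg.grid_dims, sigma=3.0)
    )
    baseline = np.clip(baseline, 0.1 * cfg.baseline_amplitude, None)
    gm_mask = _make_mask(base_rng, cfg)

    # ratings: raw per run, convolved within each run.  The scoring target
    # always uses the canonical HRF; the injected brain signal may follow an
    # HRF with a different peak delay (hemodynamic mismatch scenario).
    rate_rng = streams["ratings"]
    hrf = canonical_hrf(cfg.tr_seconds)
    Hrun = convolution_matrix(hrf, cfg.scans_per_run).H
    if cfg.signal_hrf_peak_delay_s != 6.0:
        hrf_sig = canonical_hrf(cfg.tr_seconds, peak_delay=cfg.signal_hrf_peak_delay_s)
        Hsig = convolution_matrix(hrf_sig, cfg.scans_per_run).H
    else:
        Hsig = Hrun
    raw_ratings, convolved_ratings, signal_ratings, names = [], [], [], []
    for r_idx, kind in enumerate(cfg.rating_kinds):
        params: dict = {"tr_seconds": cfg.tr_seconds}
        if kind == "block":
            params["block_length"] = cfg.block_length
        if kind == "spikes":
            params["k"] = cfg.spike_count
        z = np.concatenate(
            [
                generate_rating(kind, cfg.scans_per_run, params, rate_rng)
                for _ in range(cfg.n_runs)
            ]
        )
        t = np.concatenate(
            [Hrun @ z[start:stop] for start, stop in run_boundaries]
        )
        t_sig = (
            t
            if Hsig is Hrun
            else np.concatenate([Hsig @ z[start:stop] for start, stop in run_boundaries])
        )
        raw_ratings.append(z)
        convolved_ratings.append(t)
        signal_ratings.append(t_sig)
        names.append(f"{kind}_{r_idx}")

    weight_rng = streams["weights"]
    true_weight_maps = [
        _make_weight_map(weight_rng, cfg, gm_mask.data) for _ in cfg.rating_kinds
    ]

    volumes = np.empty(cfg.grid_dims + (n_total,))
    volumes[:] = baseline[..., None]

    # drift: per-run cosine mixtures below the configured cutoff, with
    # voxel-specific amplitude and phase (quadrature pairs of smooth random
    # fields), i.e. spatially heterogeneous like scanner drift
    drift_rng = streams["drift"]
    if cfg.drift_amplitude > 0:
        n_comp = 3
        amp = cfg.drift_amplitude / np.sqrt(n_comp)
        for start, stop in run_boundaries:
            tt = np.arange(stop - start) * cfg.tr_seconds
            for _ in range(n_comp):
                f = drift_rng.uniform(0.1 * cfg.drift_max_freq_hz, cfg.drift_max_freq_hz)
                a = _smooth_field(drift_rng, cfg.grid_dims, sigma=2.0)
                b = _smooth_field(drift_rng, cfg.grid_dims, sigma=2.0)
                a *= amp / max(a.std(), 1e-12)
                b *= amp / max(b.std(), 1e-12)
                cos_t = np.cos(2.0 * np.pi * f * tt)
                sin_t = np.sin(2.0 * np.pi * f * tt)
                volumes[..., start:stop] += (
                    a[..., None] * cos_t[None, None, None, :]
                    + b[..., None] * sin_t[None, None, None, :]
                )

    if cfg.effect_amplitude > 0:
        for w, t in zip(true_weight_maps, signal_ratings):
            volumes += cfg.effect_amplitude * w[..., None] * t[None, None, None, :]

    if cfg.noise_sd > 0:
        volumes += streams["noise"].normal(0.0, cfg.noise_sd, size=volumes.shape)

    if not np.all(np.isfinite(volumes)):
        raise FloatingPointError("generated volumes contain non-finite values")
    return SyntheticDataset(
        volumes=volumes,
        gm_mask=gm_mask,
        true_weight_maps=true_weight_maps,
        raw_ratings=raw_ratings,
        convolved_ratings=convolved_ratings,
        run_boundaries=run_boundaries,
        rating_names=names,
        config=cfg,
    )
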