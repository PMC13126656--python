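"""Synthetic inputs with ground truth for the whole analysis pipeline.

Patient OR-PAM scans of the endometrium are not publicly deposited, so this
module generates statistical stand-ins for every input the pipeline consumes:

* **Vessel phantoms** — 2D MIP-like images of tree-structured vasculature
  grown by stochastic directed walks.  Each branch carries a diameter drawn
  from a truncated normal; tubes are rendered by stamping disks of the local
  radius along the centerline, so the Euclidean distance transform at a
  centerline pixel recovers the local radius and the morphometry stage has an
  exact target.  Short isolated fragments emulate the fragmented, disconnected
  vessels seen in malignant tissue.
* **RF phantoms** — volumes whose A-lines contain Gaussian-modulated cosine
  pulses with a known spectral centroid, for validating the spectral stage.
  An optional finite absorber size low-passes the pulse (larger absorbers emit
  lower frequencies), giving a controlled, strictly monotone centroid shift.
* **Feature tables** — two-class multivariate-normal feature vectors
  (truncated at zero by rejection sampling) whose effect directions mimic the
  malignant-vs-normal contrasts the pipeline is meant to detect: lower mean
  frequency, larger and more variable diameters, more isolated branch length,
  longer branching intervals in the diseased class.

Ground truth reports the *realized* statistics of each generated object, not
the nominal spec parameters, so recovery tests are free of sampling and
rasterization error.  All outputs are deterministic functions of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .rf_preprocessing import (
    DEFAULT_PIXEL_SIZE_UM,
    MIPImage,
    RFVolume,
    ValidationError,
    write_rf_h5,
)

__all__ = [
    "VesselNetworkSpec",
    "GroundTruth",
    "RFPhantomSpec",
    "RFPhantom",
    "FeatureEffect",
    "SELECTED_FEATURES",
    "default_effects",
    "calibration_spec",
    "generate_vessel_phantom",
    "generate_rf_phantom",
    "generate_feature_table",
    "save_phantom",
    "save_rf_phantom",
]

SPEED_OF_SOUND_UM_PER_S = 1.5e9  # soft tissue, 1500 m/s

#: The five features retained by the downstream selection stage, in canonical
#: order: spectral mean frequency, diameter mean/SD, area-normalized isolated
#: branch length, and branching interval.
SELECTED_FEATURES = (
    "mean_frequency_mhz",
    "mean_diameter_um",
    "sd_diameter_um",
    "normalized_isolated_branch_length",
    "branching_interval_um",
)

LABEL_NORMAL = "normal_benign"
LABEL_DISEASE = "ec_ein"


# ---------------------------------------------------------------------------
# Vessel phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselNetworkSpec:
    """Parameters of a synthetic vascular network.

    Diameters are drawn per branch from a normal truncated below at
    ``2 * pixel_size_um`` (a vessel narrower than two pixels is not
    resolvable).  ``branch_prob_per_step`` is the per-1-px-step probability
    that a growing branch spawns a child.  ``isolated_fragment_fraction`` is
    the target fraction of total centerline length contributed by short
    fragments disconnected from the trees.
    """

    seed: int = 0
    image_size_px: tuple[int, int] = (320, 320)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_trees: int = 2
    mean_diameter_um: float = 20.0
    sd_diameter_um: float = 4.0
    branch_prob_per_step: float = 0.04
    mean_branch_length_um: float = 300.0
    max_branches_per_tree: int = 8
    direction_jitter: float = 0.08
    isolated_fragment_fraction: float = 0.1
    background_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        rows, cols = self.image_size_px
        if rows < 32 or cols < 32:
            raise ValidationError("image_size_px: each dimension must be >= 32")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.n_trees < 0:
            raise ValidationError("n_trees must be nonnegative")
        if self.mean_diameter_um < 2.0 * self.pixel_size_um:
            raise ValidationError(
                "mean_diameter_um must be >= 2 * pixel_size_um for the vessel "
                "to be resolvable"
            )
        if self.sd_diameter_um < 0:
            raise ValidationError("sd_diameter_um must be nonnegative")
        if not 0.0 <= self.branch_prob_per_step <= 1.0:
            raise ValidationError("branch_prob_per_step must be in [0, 1]")
        if self.mean_branch_length_um <= 0:
            raise ValidationError("mean_branch_length_um must be positive")
        if self.max_branches_per_tree < 1:
            raise ValidationError("max_branches_per_tree must be >= 1")
        if self.direction_jitter < 0:
            raise ValidationError("direction_jitter must be nonnegative")
        if not 0.0 <= self.isolated_fragment_fraction < 1.0:
            raise ValidationError("isolated_fragment_fraction must be in [0, 1)")
        if self.background_noise_sd < 0:
            raise ValidationError("background_noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Realized statistics of a generated network.

    Diameter statistics are measured on the clean rendering (twice the exact
    Euclidean distance transform at the generator's own centerline pixels), so
    they describe the tubes actually present in the image, free of
    rasterization bias.  ``tube_mask`` is the noise-free binary rendering.
    """

    true_mean_diameter_um: float
    true_sd_diameter_um: float
    true_n_branch_nodes: int
    true_total_centerline_length_um: float
    true_isolated_length_um: float
    centerline_mask: np.ndarray
    tube_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.true_isolated_length_um > self.true_total_centerline_length_um + 1e-9:
            raise ValidationError(
                "true_isolated_length_um exceeds true_total_centerline_length_um"
            )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    """One draw from N(mean, sd) truncated below at ``low`` (rejection)."""
    if sd == 0.0:
        return max(mean, low)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= low:
            return x
    return low


def _path_length_px(path: np.ndarray) -> float:
    """Centerline length in pixels of an ordered (k, 2) integer pixel path."""
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(path, axis=0))
    return float(np.sum(np.where(steps.max(axis=1) > 0, np.hypot(steps[:, 0], steps[:, 1]), 0.0)))


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    angle: float,
    length_px: float,
    branch_prob: float,
    shape: tuple[int, int],
    margin: float,
    jitter: float,
) -> tuple[np.ndarray, list[tuple[np.ndarray, float]]]:
    """Grow one branch: a jittered directed walk of ~unit steps.

    The walk stops at ``margin`` pixels from the border (the tube radius plus
    slack, so rendered tubes are never clipped by the frame).  Returns the
    ordered unique raster path and the (position, angle) spawn points where
    children should start.
    """
    rows, cols = shape
    pos = start.astype(float).copy()
    path: list[tuple[int, int]] = [(int(round(pos[0])), int(round(pos[1])))]
    spawns: list[tuple[np.ndarray, float]] = []
    n_steps = int(round(length_px))
    for _ in range(n_steps):
        angle += rng.normal(0.0, jitter)
        pos = pos + np.array([math.sin(angle), math.cos(angle)])
        if not (margin <= pos[0] < rows - margin and margin <= pos[1] < cols - margin):
            break
        pix = (int(round(pos[0])), int(round(pos[1])))
        if pix != path[-1]:
            path.append(pix)
        if branch_prob > 0 and rng.random() < branch_prob:
            side = 1.0 if rng.random() < 0.5 else -1.0
            spawns.append((pos.copy(), angle + side * rng.uniform(0.9, 1.5)))
    return np.array(path, dtype=np.int64), spawns


def _stamp_disks(canvas: np.ndarray, path: np.ndarray, radius_px: float) -> None:
    """Set to 1 every pixel whose center lies within ``radius_px`` of the path."""
    r = int(math.floor(radius_px))
    if r < 1:
        r = 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy * yy + xx * xx) <= radius_px * radius_px
    rows, cols = canvas.shape
    for pr, pc in path:
        r0, r1 = pr - r, pr + r + 1
        c0, c1 = pc - r, pc + r + 1
        dr0, dc0 = max(0, -r0), max(0, -c0)
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(rows, r1), min(cols, c1)
        canvas[r0:r1, c0:c1] |= disk[dr0 : dr0 + (r1 - r0), dc0 : dc0 + (c1 - c0)]


def calibration_spec(mean_diameter_um: float, seed: int = 0) -> VesselNetworkSpec:
    """Calibration-phantom conditions for diameter-recovery experiments.

    Unbranched, gently curving tubes (length 8x diameter, diameter SD 15% of
    the mean, no fragments) in a 512 px field: when projected tubes overlap
    or merge, per-pixel diameter is ill-defined, so diameter *calibration* is
    assessed on clean tubes while the branching generator exercises the
    topology stage.
    """
    return VesselNetworkSpec(
        seed=seed,
        image_size_px=(512, 512),
        n_trees=3,
        max_branches_per_tree=6,
        branch_prob_per_step=0.0,
        mean_diameter_um=mean_diameter_um,
        sd_diameter_um=0.15 * mean_diameter_um,
        mean_branch_length_um=8.0 * mean_diameter_um,
        direction_jitter=0.05,
        isolated_fragment_fraction=0.0,
    )


def generate_vessel_phantom(spec: VesselNetworkSpec) -> tuple[MIPImage, GroundTruth]:
    """Render a vascular phantom image and its realized ground truth.

    Trees are grown as stochastic directed walks; each branch's tube is the
    union of disks of its drawn radius stamped along the raster centerline.
    Isolated fragments (short straight-ish walks placed clear of the trees)
    are added until their centerline length reaches the target fraction of the
    total.  Background is additive Gaussian noise clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size_px
    px = spec.pixel_size_um
    mean_len_px = spec.mean_branch_length_um / px
    min_radius_px = 1.0  # 2-px-diameter floor: below this nothing is resolvable

    tree_paths: list[np.ndarray] = []
    tree_radii: list[float] = []
    n_branch_nodes = 0
    for _ in range(spec.n_trees):
        start = np.array(
            [rng.uniform(0.12 * rows, 0.88 * rows), rng.uniform(0.12 * cols, 0.88 * cols)],
            dtype=float,
        )
        queue: list[tuple[np.ndarray, float, int]] = [(start, rng.uniform(0, 2 * math.pi), 0)]
        n_branches_tree = 0
        while queue and n_branches_tree < spec.max_branches_per_tree:
            pos, ang, depth = queue.pop(0)
            length = mean_len_px * rng.uniform(0.6, 1.4)
            diam = _truncated_normal(
                rng, spec.mean_diameter_um, spec.sd_diameter_um, 2.0 * px
            )
            radius = max(diam / (2.0 * px), min_radius_px)
            path, spawns = _walk(
                rng, pos, ang, length, spec.branch_prob_per_step, (rows, cols),
                margin=radius + 2.0, jitter=spec.direction_jitter,
            )
            if len(path) < 2:
                continue
            tree_paths.append(path)
            tree_radii.append(radius)
            n_branches_tree += 1
            if depth > 0:
                n_branch_nodes += 1  # a realized child = one junction on its parent
            if depth == 0 and not spawns and spec.branch_prob_per_step > 0 and len(path) > 4:
                # a tree is a branching structure by construction: force one
                # child off the root when the stochastic walk spawned none
                mid = path[len(path) // 2].astype(float)
                side = 1.0 if rng.random() < 0.5 else -1.0
                spawns = [(mid, ang + side * rng.uniform(0.9, 1.5))]
            for spos, sang in spawns:
                if depth < 6:
                    queue.append((spos, sang, depth + 1))

    tree_length_px = sum(_path_length_px(p) for p in tree_paths)

    # --- isolated fragments: short walks kept clear of everything placed so far
    frag_paths: list[np.ndarray] = []
    frag_radii: list[float] = []
    iso_length_px = 0.0
    f = spec.isolated_fragment_fraction
    if f > 0 and tree_length_px > 0:
        target_px = f / (1.0 - f) * tree_length_px
        occupied = np.vstack(tree_paths) if tree_paths else np.empty((0, 2))
        max_r_px = (spec.mean_diameter_um + 4 * spec.sd_diameter_um) / (2 * px)
        attempts = 0
        while iso_length_px < target_px and attempts < 2000:
            attempts += 1
            start = np.array(
                [rng.uniform(8, rows - 8), rng.uniform(8, cols - 8)], dtype=float
            )
            length = rng.uniform(8.0, 25.0)
            diam = _truncated_normal(
                rng, spec.mean_diameter_um, spec.sd_diameter_um, 2.0 * px
            )
            radius = max(diam / (2.0 * px), min_radius_px)
            path, _ = _walk(
                rng, start, rng.uniform(0, 2 * math.pi), length, 0.0, (rows, cols),
                margin=radius + 2.0, jitter=spec.direction_jitter,
            )
            if len(path) < 2:
                continue
            clearance = radius + max_r_px + 3.0
            if occupied.size:
                d2 = (
                    (occupied[:, 0][None, :] - path[:, 0][:, None]) ** 2
                    + (occupied[:, 1][None, :] - path[:, 1][:, None]) ** 2
                )
                if d2.min() < clearance * clearance:
                    continue
            frag_paths.append(path)
            frag_radii.append(radius)
            occupied = np.vstack([occupied, path]) if occupied.size else path
            iso_length_px += _path_length_px(path)

    # --- render
    tube = np.zeros((rows, cols), dtype=bool)
    for path, radius in zip(tree_paths + frag_paths, tree_radii + frag_radii):
        _stamp_disks(tube, path, radius)
    centerline = np.zeros((rows, cols), dtype=bool)
    for path in tree_paths + frag_paths:
        centerline[path[:, 0], path[:, 1]] = True

    image = tube.astype(np.float64)
    if spec.background_noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, spec.background_noise_sd, image.shape), 0.0, None)

    # --- realized diameter statistics: 2 x exact EDT on the clean rendering
    if tube.any():
        edt = ndimage.distance_transform_edt(tube)
        diam_um = 2.0 * edt[centerline] * px
        mean_d = float(diam_um.mean()) if diam_um.size else 0.0
        sd_d = float(diam_um.std(ddof=1)) if diam_um.size > 1 else 0.0
    else:
        mean_d, sd_d = 0.0, 0.0

    total_len_px = tree_length_px + iso_length_px
    gt = GroundTruth(
        true_mean_diameter_um=mean_d,
        true_sd_diameter_um=sd_d,
        true_n_branch_nodes=n_branch_nodes,
        true_total_centerline_length_um=total_len_px * px,
        true_isolated_length_um=iso_length_px * px,
        centerline_mask=centerline,
        tube_mask=tube,
    )
    return MIPImage(image, pixel_size_um=px), gt


# ---------------------------------------------------------------------------
# RF phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFPhantomSpec:
    """Gaussian-modulated cosine pulse phantom for an RF C-scan.

    ``gaussian_bandwidth_hz`` is the standard deviation of the Gaussian power
    envelope in the frequency domain; the time-domain envelope width is
    ``1 / (2 pi * bandwidth)``.  ``absorber_positions`` lists
    ``(lateral, frame, sample)`` triples; every listed A-line receives a pulse
    centered at the given time sample.  A positive ``absorber_diameter_um``
    low-passes the emitted pulse with a Gaussian of time constant
    ``d / (2 c)`` — the finite-size-absorber effect that shifts spectral
    content downward.
    """

    seed: int = 0
    sampling_rate_hz: float = 250e6
    n_samples_per_aline: int = 1024
    carrier_freq_hz: float = 40e6
    gaussian_bandwidth_hz: float = 15e6
    absorber_positions: tuple[tuple[int, int, int], ...] = ((0, 0, 512),)
    amplitude: float = 1.0
    noise_sd: float = 0.0
    n_lateral: int = 8
    n_frames: int = 8
    absorber_diameter_um: float = 0.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.carrier_freq_hz >= self.sampling_rate_hz / 2:
            raise ValidationError(
                "carrier_freq_hz must be below Nyquist (sampling_rate_hz / 2)"
            )
        if self.carrier_freq_hz <= 0:
            raise ValidationError("carrier_freq_hz must be positive")
        if self.gaussian_bandwidth_hz <= 0:
            raise ValidationError("gaussian_bandwidth_hz must be positive")
        if self.n_samples_per_aline < 16:
            raise ValidationError("n_samples_per_aline must be >= 16")
        if self.n_lateral < 1 or self.n_frames < 1:
            raise ValidationError("n_lateral and n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.absorber_diameter_um < 0:
            raise ValidationError("absorber_diameter_um must be nonnegative")
        for lat, frm, smp in self.absorber_positions:
            if not (0 <= lat < self.n_lateral and 0 <= frm < self.n_frames):
                raise ValidationError(
                    f"absorber position ({lat}, {frm}) outside the {self.n_lateral}"
                    f"x{self.n_frames} grid"
                )
            if not 0 <= smp < self.n_samples_per_aline:
                raise ValidationError(f"absorber sample index {smp} out of range")


@dataclass(frozen=True)
class RFPhantom:
    """Generated RF volume plus the oracle pulse and its spectral centroid.

    ``analytic_centroid_hz`` is the power-weighted mean frequency of the
    noise-free prototype pulse, computed by direct FFT; it is NaN when the
    amplitude is zero (no signal: mean frequency undefined).
    """

    volume: RFVolume
    analytic_centroid_hz: float
    pulse: np.ndarray
    pulse_center_sample: int


def _prototype_pulse(spec: RFPhantomSpec) -> np.ndarray:
    """Noise-free pulse waveform on the A-line time grid, centered mid-line."""
    n = spec.n_samples_per_aline
    fs = spec.sampling_rate_hz
    t = (np.arange(n) - n // 2) / fs
    sigma_t = 1.0 / (2.0 * math.pi * spec.gaussian_bandwidth_hz)
    pulse = spec.amplitude * np.exp(-(t**2) / (2 * sigma_t**2)) * np.cos(
        2 * math.pi * spec.carrier_freq_hz * t
    )
    if spec.absorber_diameter_um > 0:
        tau_s = spec.absorber_diameter_um / (2.0 * SPEED_OF_SOUND_UM_PER_S)
        pulse = ndimage.gaussian_filter1d(pulse, sigma=tau_s * fs, mode="constant")
    return pulse


def spectral_centroid_fft(signal: np.ndarray, fs_hz: float) -> float:
    """Power-weighted mean frequency of a real signal, by direct rFFT."""
    power = np.abs(np.fft.rfft(signal)) ** 2
    total = power.sum()
    if total <= 0:
        return float("nan")
    freqs = np.fft.rfftfreq(len(signal), d=1.0 / fs_hz)
    return float((freqs * power).sum() / total)


def generate_rf_phantom(spec: RFPhantomSpec) -> RFPhantom:
    """Place the prototype pulse on each listed A-line and add white noise."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples_per_aline
    vol = np.zeros((n, spec.n_lateral, spec.n_frames), dtype=np.float64)
    pulse = _prototype_pulse(spec)
    center = n // 2
    for lat, frm, smp in spec.absorber_positions:
        shifted = np.roll(pulse, smp - center)
        # roll wraps; zero the wrapped-around part
        if smp < center:
            shifted[n - (center - smp) :] = 0.0
        elif smp > center:
            shifted[: smp - center] = 0.0
        vol[:, lat, frm] += shifted
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, vol.shape)
    centroid = spectral_centroid_fft(pulse, spec.sampling_rate_hz)
    return RFPhantom(
        volume=RFVolume(vol, spec.sampling_rate_hz, spec.pixel_size_um),
        analytic_centroid_hz=centroid,
        pulse=pulse,
        pulse_center_sample=center,
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureEffect:
    """Class-conditional distribution of one feature.

    The normal/benign class is N(mean_normal, sd); the diseased class mean is
    shifted by ``shift_sd`` standard deviations (signed).
    """

    mean_normal: float
    sd: float
    shift_sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError("feature sd must be positive")

    @property
    def mean_disease(self) -> float:
        return self.mean_normal + self.shift_sd * self.sd


def default_effects(effect_size_sd: float = 1.5) -> dict[str, FeatureEffect]:
    """Default two-class structure of the five selected features.

    Effect *directions* follow the disease biology the pipeline targets:
    malignant/premalignant tissue shows a lower spectral mean frequency
    (enlarged absorbers), larger and more variable vessel diameters, more
    area-normalized isolated branch length (fragmentation), and longer
    branching intervals (sparser junctions).  ``effect_size_sd`` scales the
    magnitude of every shift; 0 gives a null table.
    """
    d = effect_size_sd
    return {
        "mean_frequency_mhz": FeatureEffect(32.0, 3.0, -d),
        "mean_diameter_um": FeatureEffect(35.0, 8.0, +d),
        "sd_diameter_um": FeatureEffect(10.0, 3.0, +d),
        "normalized_isolated_branch_length": FeatureEffect(2.0e-4, 0.8e-4, +d),
        "branching_interval_um": FeatureEffect(120.0, 40.0, +d),
    }


def generate_feature_table(
    n_per_class: tuple[int, int],
    effects: dict[str, FeatureEffect] | None = None,
    correlation: float = 0.3,
    seed: int = 0,
    n_noise_features: int = 0,
) -> pd.DataFrame:
    """Two-class feature table: class-wise multivariate normal, truncated at 0.

    Parameters
    ----------
    n_per_class
        ``(n_normal_benign, n_ec_ein)`` row counts.
    effects
        Per-feature class-conditional distributions; defaults to
        :func:`default_effects`.
    correlation
        Common pairwise correlation of the latent normal within each class.
    n_noise_features
        Extra uninformative nonnegative features (``noise_00`` ...) appended
        after the named set, for feature-screening tests.

    Rows with any negative latent draw are rejected and redrawn, so every
    feature is nonnegative.  Identical arguments give identical tables.
    """
    if effects is None:
        effects = default_effects()
    names = list(effects)
    p = len(names)
    if not -1.0 / max(p - 1, 1) < correlation < 1.0:
        raise ValidationError("correlation outside the positive-definite range")
    rng = np.random.default_rng(seed)
    corr = np.full((p, p), correlation)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    sds = np.array([effects[f].sd for f in names])

    rows = []
    labels = []
    for label, n, means in (
        (LABEL_NORMAL, n_per_class[0], np.array([effects[f].mean_normal for f in names])),
        (LABEL_DISEASE, n_per_class[1], np.array([effects[f].mean_disease for f in names])),
    ):
        for _ in range(n):
            for _attempt in range(10000):
                z = chol @ rng.standard_normal(p)
                x = means + sds * z
                if np.all(x >= 0):
                    break
            else:
                raise ValidationError(
                    "rejection sampling failed: means too far below zero"
                )
            rows.append(x)
            labels.append(label)

    df = pd.DataFrame(rows, columns=names)
    for j in range(n_noise_features):
        df[f"noise_{j:02d}"] = np.abs(rng.standard_normal(len(df)))
    df["label"] = labels
    return df


# ---------------------------------------------------------------------------
# File export
# ---------------------------------------------------------------------------

def save_phantom(out_dir: str | Path, name: str, mip: MIPImage, gt: GroundTruth) -> None:
    """Write phantom image (16-bit TIFF) and ground truth (JSON sidecar)."""
    from .rf_preprocessing import write_mip_tiff

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mip_tiff(out_dir / f"{name}.tif", mip)
    sidecar = {
        "true_mean_diameter_um": gt.true_mean_diameter_um,
        "true_sd_diameter_um": gt.true_sd_diameter_um,
        "true_n_branch_nodes": gt.true_n_branch_nodes,
        "true_total_centerline_length_um": gt.true_total_centerline_length_um,
        "true_isolated_length_um": gt.true_isolated_length_um,
    }
    (out_dir / f"{name}.json").write_text(json.dumps(sidecar, indent=2))


def save_rf_phantom(out_dir: str | Path, name: str, phantom: RFPhantom) -> None:
    """Write an RF phantom volume as an HDF5 container plus oracle sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_rf_h5(out_dir / f"{name}.h5", phantom.volume)
    (out_dir / f"{name}.json").write_text(
        json.dumps({"analytic_centroid_hz": phantom.analytic_centroid_hz})
    )
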