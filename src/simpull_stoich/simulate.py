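"""Ground-truth-annotated synthetic SiMPull acquisitions.

Emulates continuous two-channel TIRF imaging of surface-immobilized
bait:prey complexes: each complex carries one (by default) green
fluorophore on the bait and 0..k far-red fluorophores on bound prey
copies. Fluorophores photobleach memorylessly (exponential waiting
times parameterized by a per-channel bleach half-time expressed as a
fraction of the movie length), producing stepwise, sustained intensity
drops well above camera read noise; occasional blinking/re-binding
events insert transient upward steps.

Everything downstream (spot detection, colocalization, step counting,
CNN training, stoichiometry summaries) is testable against the returned
ground truth without any external data.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core import (GREEN, FARRED, GREEN_CLASSES, FARRED_CLASSES, TirfMovie,
                   derive_seed)

__all__ = [
    "AcquisitionParams", "StoichModel", "GroundTruthTable",
    "simulate_complexes", "simulate_traces", "render_movie",
    "make_affine", "make_labeled_traces", "SimulatedAcquisition",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition and camera model parameters.

    Defaults follow continuous dual-excitation imaging at 20 frames/s
    for 50 s (1000 frames per channel), with the far-red bleach
    half-time tuned to ~1/5 of the total imaging time and the green to
    ~1/10. Step amplitudes (~120 counts) sit well above read noise
    (8 counts) so that a 25-count step criterion is meaningful.
    """

    frame_rate: float = 20.0           # frames / s
    n_frames: int = 1000               # frames per channel
    pixel_size: float = 108.0          # nm / pixel
    image_shape: tuple[int, int] = (256, 256)
    psf_sigma: float = 1.3             # pixels
    baseline_offset: float = 200.0     # camera counts
    read_noise_sd: float = 8.0         # counts
    step_amplitude_mean: float = 120.0  # counts per fluorophore
    step_amplitude_sd: float = 24.0    # counts (20% of mean)
    green_halftime_frac: float = 0.10  # fraction of total imaging time
    farred_halftime_frac: float = 0.20
    blink_rate: float = 0.05           # upward-step events / trace / movie
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for name in ("green_halftime_frac", "farred_halftime_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.step_amplitude_mean <= 0:
            raise ValueError("step_amplitude_mean must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.read_noise_sd < 0 or self.step_amplitude_sd < 0:
            raise ValueError("noise/sd parameters must be non-negative")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be non-negative")

    def halftime_frac(self, channel: str) -> float:
        return (self.green_halftime_frac if channel == GREEN
                else self.farred_halftime_frac)

    def bleach_rate(self, channel: str) -> float:
        """Per-frame exponential bleaching rate lambda = ln2 / half-time."""
        return math.log(2.0) / (self.halftime_frac(channel) * self.n_frames)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionParams":
        d = json.loads(Path(path).read_text())
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


def _check_pmf(p: dict[int, float], name: str) -> None:
    if not p:
        raise ValueError(f"{name} must be non-empty")
    if any(k < 0 for k in p):
        raise ValueError(f"{name} keys must be non-negative counts")
    if any(v < 0 for v in p.values()):
        raise ValueError(f"{name} probabilities must be non-negative")
    if abs(sum(p.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1")


@dataclass(frozen=True)
class StoichModel:
    """Per-complex fluorophore-count distributions.

    ``p_green`` defaults to a single green fluorophore per complex (one
    bait molecule); ``p_farred`` to a mixture with a 40% oligomeric
    fraction (>= 2 prey copies among labeled complexes).
    ``labeling_efficiency`` thins each far-red site independently; with
    no measured dye efficiency, observed prey counts are a lower bound
    on true copy number, so the default is 1 (no correction).
    """

    p_green: dict = field(default_factory=lambda: {1: 1.0})
    p_farred: dict = field(default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    labeling_efficiency: float = 1.0

    def __post_init__(self) -> None:
        _check_pmf(self.p_green, "p_green")
        _check_pmf(self.p_farred, "p_farred")
        if not 0 <= self.labeling_efficiency <= 1:
            raise ValueError("labeling_efficiency must be in [0, 1]")


@dataclass
class GroundTruthTable:
    """Per-complex ground truth, filled in as the simulation proceeds.

    ``fluorophores`` (one row per fluorophore: complex_id, channel,
    amplitude, bleach_frame) and ``blink_events`` are populated by
    :func:`simulate_traces`. Bleach frames are realized exponential
    waiting times and may exceed ``n_frames`` (the fluorophore then
    survives the whole movie; its bleach is censored).
    """

    positions: np.ndarray                  # (n, 2) subpixel (row, col), green coords
    green_count: np.ndarray                # (n,) int
    farred_count: np.ndarray               # (n,) int
    complex_id: np.ndarray | None = None
    fluorophores: pd.DataFrame | None = None
    blink_events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.green_count = np.asarray(self.green_count, dtype=int)
        self.farred_count = np.asarray(self.farred_count, dtype=int)
        if self.complex_id is None:
            self.complex_id = np.arange(len(self.green_count))
        if (self.green_count < 0).any() or (self.farred_count < 0).any():
            raise ValueError("fluorophore counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.complex_id)

    def counts(self, channel: str) -> np.ndarray:
        return self.green_count if channel == GREEN else self.farred_count

    def write(self, directory: str | Path, prefix: str = "truth") -> None:
        directory = Path(directory)
        per_complex = pd.DataFrame({
            "complex_id": self.complex_id,
            "position_row": self.positions[:, 0],
            "position_col": self.positions[:, 1],
            "green_count": self.green_count,
            "farred_count": self.farred_count,
        })
        per_complex.to_csv(directory / f"{prefix}_complexes.csv", index=False)
        if self.fluorophores is not None:
            fl = self.fluorophores.merge(
                per_complex[["complex_id", "position_row", "position_col"]],
                on="complex_id")
            fl.to_csv(directory / f"{prefix}_fluorophores.csv", index=False)
        if self.blink_events is not None:
            self.blink_events.to_csv(directory / f"{prefix}_blinks.csv",
                                     index=False)


def _sample_categorical(p: dict[int, float], n: int,
                        rng: np.random.Generator) -> np.ndarray:
    keys = np.array(sorted(p.keys()), dtype=int)
    probs = np.array([p[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=n, p=probs)


def simulate_complexes(model: StoichModel, n: int,
                       image_shape: tuple[int, int] = (256, 256),
                       min_separation: float = 4.0,
                       seed: int | None = 0,
                       margin: float = 6.0,
                       max_attempts: int | None = None) -> GroundTruthTable:
    """Place ``n`` complexes with pairwise separation >= ``min_separation``.

    Positions are rejection-sampled uniformly inside the field (with a
    border ``margin`` so every spot keeps a full extraction window);
    fluorophore counts are i.i.d. from ``model``, with far-red counts
    thinned binomially by the labeling efficiency.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if min_separation < 0:
        raise ValueError("min_separation must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    lo, hi_r, hi_c = margin, h - 1 - margin, w - 1 - margin
    if n > 0 and (hi_r <= lo or hi_c <= lo):
        raise ValueError("image too small for the requested margin")
    if max_attempts is None:
        max_attempts = max(10_000, 500 * n)

    accepted = np.empty((n, 2))
    count, attempts = 0, 0
    while count < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} complexes at separation "
                f"{min_separation} after {max_attempts} attempts")
        attempts += 1
        cand = np.array([rng.uniform(lo, hi_r), rng.uniform(lo, hi_c)])
        if count and min_separation > 0:
            d2 = np.sum((accepted[:count] - cand) ** 2, axis=1)
            if d2.min() < min_separation ** 2:
                continue
        accepted[count] = cand
        count += 1

    green = _sample_categorical(model.p_green, n, rng)
    farred_raw = _sample_categorical(model.p_farred, n, rng)
    if model.labeling_efficiency < 1.0:
        farred = rng.binomial(farred_raw, model.labeling_efficiency)
    else:
        farred = farred_raw
    return GroundTruthTable(positions=accepted, green_count=green,
                            farred_count=farred)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def realize_photophysics(truth: GroundTruthTable, acq: AcquisitionParams,
                         seed: int | None = None) -> GroundTruthTable:
    """Draw per-fluorophore amplitudes, bleach times and blink events.

    Idempotent: if ``truth.fluorophores`` is already populated the
    stored realization is kept so traces and rendered movies agree.
    """
    if truth.fluorophores is not None:
        return truth
    rng = np.random.default_rng(acq.seed if seed is None else seed)
    mu, sigma = _lognormal_params(acq.step_amplitude_mean,
                                  acq.step_amplitude_sd)
    rows = []
    blink_rows = []
    for channel in (GREEN, FARRED):
        rate = acq.bleach_rate(channel)
        counts = truth.counts(channel)
        for cid, c in zip(truth.complex_id, counts):
            if c == 0:
                amps = np.empty(0)
                bleach = np.empty(0)
            else:
                amps = rng.lognormal(mu, sigma, size=c)
                bleach = rng.exponential(1.0 / rate, size=c)
            for a, b in zip(amps, bleach):
                rows.append((cid, channel, float(a), float(b)))
            # blinking: a previously bleached fluorophore transiently re-appears
            n_blinks = rng.poisson(acq.blink_rate)
            for _ in range(n_blinks):
                done = bleach[bleach < acq.n_frames - 1]
                if done.size == 0:
                    continue
                idx = rng.integers(done.size)
                t_bleach = done[idx]
                amp = amps[np.flatnonzero(bleach < acq.n_frames - 1)[idx]]
                start = rng.uniform(t_bleach + 1, acq.n_frames)
                duration = rng.geometric(1.0 / 20.0)  # mean 20 frames
                blink_rows.append((cid, channel, float(amp),
                                   float(start), int(duration)))
    truth.fluorophores = pd.DataFrame(
        rows, columns=["complex_id", "channel", "amplitude", "bleach_frame"])
    truth.blink_events = pd.DataFrame(
        blink_rows, columns=["complex_id", "channel", "amplitude",
                             "frame", "duration"])
    return truth


def signal_traces(truth: GroundTruthTable, acq: AcquisitionParams,
                  channel: str) -> np.ndarray:
    """Noise-free signal (counts above baseline) per complex per frame."""
    if truth.fluorophores is None:
        raise ValueError("photophysics not realized; call realize_photophysics")
    out = np.zeros((truth.n, acq.n_frames))
    index = {cid: i for i, cid in enumerate(truth.complex_id)}
    fl = truth.fluorophores
    sel = fl[fl["channel"] == channel] if len(fl) else fl
    for cid, amp, bleach in zip(sel["complex_id"], sel["amplitude"],
                                sel["bleach_frame"]):
        out[index[cid], : min(acq.n_frames, int(np.ceil(bleach)))] += amp
    if truth.blink_events is not None and len(truth.blink_events):
        bl = truth.blink_events[truth.blink_events["channel"] == channel]
        for cid, amp, start, dur in zip(bl["complex_id"], bl["amplitude"],
                                        bl["frame"], bl["duration"]):
            a = int(np.ceil(start))
            b = min(acq.n_frames, a + int(dur))
            out[index[cid], a:b] += amp
    return out


def simulate_traces(truth: GroundTruthTable, acq: AcquisitionParams,
                    seed: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray, GroundTruthTable]:
    """Simulate raw integrated intensity traces for every complex.

    Returns ``(green, farred, truth)`` where each trace array has shape
    ``(n_complexes, n_frames)`` in camera counts: the sum of surviving
    fluorophore amplitudes plus ``baseline_offset`` plus Gaussian read
    noise. The returned truth table carries the realized amplitudes,
    bleach frames and blink events.
    """
    seed = acq.seed if seed is None else seed
    realize_photophysics(truth, acq, seed=derive_seed(seed, "photophysics"))
    rng = np.random.default_rng(derive_seed(seed, "trace-noise"))
    out = []
    for channel in (GREEN, FARRED):
        sig = signal_traces(truth, acq, channel) + acq.baseline_offset
        if acq.read_noise_sd > 0:
            sig = sig + rng.normal(0.0, acq.read_noise_sd, size=sig.shape)
        out.append(sig)
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# movie rendering


def make_affine(translation: tuple[float, float] = (0.0, 0.0),
                rotation_deg: float = 0.0,
                scale: float = 1.0,
                center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Build a 2x3 affine matrix acting on (row, col) coordinates."""
    th = math.radians(rotation_deg)
    r = scale * np.array([[math.cos(th), -math.sin(th)],
                          [math.sin(th), math.cos(th)]])
    c = np.asarray(center, dtype=float)
    t = np.asarray(translation, dtype=float) + c - r @ c
    return np.hstack([r, t[:, None]])


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return points @ matrix[:, :2].T + matrix[:, 2]


def _pixel_gauss(centers: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Mass of a unit Gaussian integrated over unit pixels at ``centers``."""
    return (ndtr((centers + 0.5 - mu) / sigma)
            - ndtr((centers - 0.5 - mu) / sigma))


def gaussian_mass_window(sigma: float, half: int = 2,
                         offset: tuple[float, float] = (0.0, 0.0)) -> float:
    """Closed-form PSF mass inside a (2*half+1)^2 pixel window."""
    r = np.arange(-half, half + 1)
    return float(_pixel_gauss(r, offset[0], sigma).sum()
                 * _pixel_gauss(r, offset[1], sigma).sum())


def _render_stack(positions: np.ndarray, signals: np.ndarray,
                  shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Render per-frame integrated-Gaussian spot photons (no camera model)."""
    n_frames = signals.shape[1]
    h, w = shape
    stack = np.zeros((n_frames, h, w), dtype=np.float32)
    half = int(math.ceil(4 * sigma))
    for pos, sig in zip(positions, signals):
        r0, c0 = int(round(pos[0])), int(round(pos[1]))
        rows = np.arange(max(0, r0 - half), min(h, r0 + half + 1))
        cols = np.arange(max(0, c0 - half), min(w, c0 + half + 1))
        patch = np.outer(_pixel_gauss(rows, pos[0], sigma),
                         _pixel_gauss(cols, pos[1], sigma)).astype(np.float32)
        stack[:, rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1] += (
            sig.astype(np.float32)[:, None, None] * patch[None])
    return stack


def _apply_camera_noise(stack: np.ndarray, baseline: float, read_sd: float,
                        shot: bool, rng: np.random.Generator,
                        chunk: int = 100) -> np.ndarray:
    """Camera model: Poisson shot noise on signal photons, then the
    electronic baseline offset, then Gaussian read noise."""
    for a in range(0, stack.shape[0], chunk):
        b = min(a + chunk, stack.shape[0])
        block = stack[a:b]
        if shot:
            block = rng.poisson(np.clip(block, 0, None)).astype(np.float32)
        block = block + np.float32(baseline)
        if read_sd > 0:
            block = block + rng.normal(0, read_sd,
                                       size=block.shape).astype(np.float32)
        stack[a:b] = block
    return stack


@dataclass
class SimulatedAcquisition:
    """One simulated field: two movies, a bead registration pair, truth."""

    green: TirfMovie
    farred: TirfMovie
    beads_green: np.ndarray
    beads_farred: np.ndarray
    channel_offset: np.ndarray
    truth: GroundTruthTable
    acq: AcquisitionParams

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.green.write(directory / "green.tif")
        self.farred.write(directory / "farred.tif")
        import tifffile
        tifffile.imwrite(directory / "beads_green.tif",
                         self.beads_green.astype(np.float32))
        tifffile.imwrite(directory / "beads_farred.tif",
                         self.beads_farred.astype(np.float32))
        self.truth.write(directory)
        self.acq.to_json(directory / "acquisition.json")
        np.savetxt(directory / "channel_offset.csv", self.channel_offset,
                   delimiter=",")


def render_movie(truth: GroundTruthTable, acq: AcquisitionParams,
                 channel_offset: np.ndarray | None = None,
                 seed: int | None = None, *, shot_noise: bool = True,
                 n_beads: int = 15,
                 bead_amplitude: float = 2000.0) -> SimulatedAcquisition:
    """Render two-channel movies plus a fiducial-bead registration pair.

    Each complex is drawn per frame as a pixel-integrated 2-D Gaussian
    of width ``psf_sigma`` scaled to its current noise-free trace value;
    far-red coordinates are green coordinates mapped through
    ``channel_offset`` (an affine 2x3 matrix, identity by default).
    Poisson shot noise is applied to the expected counts, then Gaussian
    read noise. The bead pair is related by the same transform.
    """
    seed = acq.seed if seed is None else seed
    if channel_offset is None:
        channel_offset = make_affine()
    channel_offset = np.asarray(channel_offset, dtype=float)
    if channel_offset.shape != (2, 3):
        raise ValueError("channel_offset must be a 2x3 affine matrix")
    h, w = acq.image_shape

    realize_photophysics(truth, acq, seed=derive_seed(seed, "photophysics"))
    rng = np.random.default_rng(derive_seed(seed, "render-noise"))

    movies = {}
    for channel in (GREEN, FARRED):
        pos = truth.positions
        if channel == FARRED:
            pos = apply_affine(channel_offset, pos)
            bad = ((pos[:, 0] < 0) | (pos[:, 0] > h - 1)
                   | (pos[:, 1] < 0) | (pos[:, 1] > w - 1))
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} complexes map outside the far-red "
                    "field after the channel offset")
        sig = signal_traces(truth, acq, channel)
        stack = _render_stack(pos, sig, (h, w), acq.psf_sigma)
        stack = _apply_camera_noise(stack, acq.baseline_offset,
                                    acq.read_noise_sd, shot_noise, rng)
        movies[channel] = TirfMovie(frames=stack, channel=channel,
                                    frame_rate=acq.frame_rate,
                                    pixel_size=acq.pixel_size)

    # fiducial beads, bright in both channels, related by the same transform
    bead_rng = np.random.default_rng(derive_seed(seed, "beads"))
    margin = float(np.clip(0.08 * min(h, w), 3.0, 10.0))
    bead_sep = float(np.clip(min(h, w) / 10.0, 4.0, 10.0))
    beads = []
    attempts = 0
    while len(beads) < n_beads and attempts < 20_000:
        attempts += 1
        cand = np.array([bead_rng.uniform(margin, h - 1 - margin),
                         bead_rng.uniform(margin, w - 1 - margin)])
        mapped = apply_affine(channel_offset, cand)[0]
        if not (2 <= mapped[0] <= h - 3 and 2 <= mapped[1] <= w - 3):
            continue
        if beads and np.min(np.sum((np.array(beads) - cand) ** 2, 1)) \
                < bead_sep ** 2:
            continue
        beads.append(cand)
    beads = np.array(beads)
    if len(beads) < n_beads:
        raise RuntimeError("could not place bead fiducials")
    amp = np.full((len(beads), 1), bead_amplitude)
    bg = _render_stack(beads, amp, (h, w), acq.psf_sigma)
    bf = _render_stack(apply_affine(channel_offset, beads), amp, (h, w),
                       acq.psf_sigma)
    bg = _apply_camera_noise(bg, acq.baseline_offset, acq.read_noise_sd,
                             shot_noise, bead_rng)
    bf = _apply_camera_noise(bf, acq.baseline_offset, acq.read_noise_sd,
                             shot_noise, bead_rng)

    return SimulatedAcquisition(green=movies[GREEN], farred=movies[FARRED],
                                beads_green=bg[0], beads_farred=bf[0],
                                channel_offset=channel_offset, truth=truth,
                                acq=acq)


# ---------------------------------------------------------------------------
# labeled trace sets for classifier training


def _counts_for_class(label: str, channel: str,
                      rng: np.random.Generator) -> int:
    if channel == FARRED:
        return {"rejected": 0, "1-step": 1, "2-step": 2,
                "3-and-higher": int(rng.integers(3, 5))}[label]
    return {"rejected": int(rng.choice([0, 2])), "1-step": 1}[label]


def make_labeled_traces(n: int, channel: str = FARRED,
                        acq: AcquisitionParams | None = None,
                        class_probs: dict[str, float] | None = None,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Generate raw traces with ground-truth class labels for one channel.

    Labels derive from the true fluorophore count (0 -> rejected,
    1/2 -> 1-/2-step, >=3 -> 3-and-higher; for green, exactly 1 -> 1-step,
    otherwise rejected). Classes are sampled uniformly unless
    ``class_probs`` is given. Returns ``(traces, labels)`` with traces of
    shape ``(n, n_frames)`` in raw camera counts.
    """
    acq = acq or AcquisitionParams()
    classes = GREEN_CLASSES if channel == GREEN else FARRED_CLASSES
    if class_probs is None:
        class_probs = {c: 1.0 / len(classes) for c in classes}
    rng = np.random.default_rng(derive_seed(seed, "labels", channel))
    labels = rng.choice(list(class_probs.keys()), size=n,
                        p=np.array(list(class_probs.values()))
                        / sum(class_probs.values()))
    counts = np.array([_counts_for_class(l, channel, rng) for l in labels])
    dummy_pos = np.tile([[float(acq.image_shape[0]) / 2,
                          float(acq.image_shape[1]) / 2]], (n, 1))
    truth = GroundTruthTable(
        positions=dummy_pos,
        green_count=counts if channel == GREEN else np.zeros(n, int),
        farred_count=counts if channel == FARRED else np.zeros(n, int))
    green, farred, _ = simulate_traces(truth, acq,
                                       seed=derive_seed(seed, "traces",
                                                        channel))
    traces = green if channel == GREEN else farred
    return traces, labels
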