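"""Synthetic dual-view VSD recordings with known ground truth.

The generator emulates the statistical structure that the downstream
analysis assumes: two cameras viewing the ventral and dorsal cell-body
surfaces of a leech segmental ganglion, per-cell membrane-potential
programs (behavioral oscillations, stimulus-locked responses, spikes,
EPSPs), a linear voltage-to-fluorescence forward model, photobleaching,
a shared multiplicative global fluctuation, photon shot noise, and slow
sub-pixel rigid motion of each view.

Every quantity the analysis modules later estimate — motion trajectories,
coherence phase and magnitude, left/right response differences, cell
identities — is recorded in the ground truth of the returned
:class:`DualRecording`, so each stage of the pipeline can be verified
without real data.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Neuron",
    "CanonicalMap",
    "OscillationTerm",
    "CellProgram",
    "ActivityProgram",
    "ImagingParams",
    "StimulusProtocol",
    "DualRecording",
    "generate_canonical_map",
    "default_program",
    "simulate_voltages",
    "render_recording",
    "write_recording",
]

SURFACES = ("ventral", "dorsal")

# Canonical half-extents of the cell-body shell, in micrometres.  A ganglion
# is roughly an ellipse elongated along the animal's left-right axis; these
# values let a whole aspect fit inside a 512 x 128 pixel frame at 1 um/px.
_X_HALF_UM = 230.0
_Y_HALF_UM = 55.0


class ParameterError(ValueError):
    """A generator parameter is outside its documented range."""


class ConsistencyError(ValueError):
    """Mutually inconsistent inputs (e.g. mismatched lengths)."""


# ---------------------------------------------------------------------------
# Canonical map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Neuron:
    """One identified neuron of the canonical map."""

    id: str
    surface: str            # "ventral" | "dorsal"
    packet: int             # glial packet, 1..6
    x: float                # canonical coordinates, um; x=0 is the midline
    y: float
    radius: float           # soma radius, um
    homolog_id: str | None  # bilateral partner, if any


@dataclass
class CanonicalMap:
    """Chart of identified neuron positions/sizes on both surfaces."""

    neurons: list[Neuron]

    def __post_init__(self) -> None:
        ids = [n.id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise ParameterError("neuron ids must be unique")
        by_id = {n.id: n for n in self.neurons}
        for n in self.neurons:
            if n.radius <= 0:
                raise ParameterError(f"neuron {n.id}: radius must be > 0")
            if n.surface not in SURFACES:
                raise ParameterError(f"neuron {n.id}: unknown surface {n.surface!r}")
            if not 1 <= n.packet <= 6:
                raise ParameterError(f"neuron {n.id}: packet must be in 1..6")
            if n.homolog_id is not None:
                partner = by_id.get(n.homolog_id)
                if partner is None or partner.homolog_id != n.id:
                    raise ParameterError(
                        f"neuron {n.id}: homolog pairing is not symmetric"
                    )
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.neurons)

    def __getitem__(self, neuron_id: str) -> Neuron:
        return self._by_id[neuron_id]

    def camera_view(self, surface: str) -> "CanonicalMap":
        """The chart of one surface as its camera sees it.

        The dorsal camera faces the opposite side of the ganglion, so its
        image is left-right mirrored relative to canonical anatomical
        coordinates; this returns the surface subset with x negated for
        the dorsal aspect, so registration never needs a reflection.
        """
        sub = self.surface_subset(surface)
        if surface == "ventral":
            return sub
        return CanonicalMap([
            Neuron(n.id, n.surface, n.packet, -n.x, n.y, n.radius, n.homolog_id)
            for n in sub.neurons
        ])

    def surface_subset(self, surface: str) -> "CanonicalMap":
        """Neurons of one surface, with cross-surface homolog links kept."""
        kept = [n for n in self.neurons if n.surface == surface]
        kept_ids = {n.id for n in kept}
        out = []
        for n in kept:
            hid = n.homolog_id if n.homolog_id in kept_ids else None
            out.append(Neuron(n.id, n.surface, n.packet, n.x, n.y, n.radius, hid))
        return CanonicalMap(out)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(n) for n in self.neurons]).set_index("id")

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe().rename(
            columns={"surface": "aspect", "x": "x_um", "y": "y_um",
                     "radius": "radius_um"}
        )
        df.index.name = "neuron_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CanonicalMap":
        df = pd.read_csv(path).set_index("neuron_id")
        neurons = [
            Neuron(
                id=str(i),
                surface=row["aspect"],
                packet=int(row["packet"]),
                x=float(row["x_um"]),
                y=float(row["y_um"]),
                radius=float(row["radius_um"]),
                homolog_id=None if pd.isna(row["homolog_id"]) else str(row["homolog_id"]),
            )
            for i, row in df.iterrows()
        ]
        return cls(neurons)


def _packet_of(x: float, y: float) -> int:
    """Six glia-bounded packets: anterior/middle/posterior x left/right."""
    band = 0 if y < -_Y_HALF_UM / 3 else (1 if y < _Y_HALF_UM / 3 else 2)
    side = 0 if x < 0 else 1
    return 1 + 2 * band + side


def generate_canonical_map(n_per_surface: int, seed: int) -> CanonicalMap:
    """Generate a canonical map with ``n_per_surface`` neurons per surface.

    Neurons are laid out inside an elliptical shell region, mostly as
    bilateral homolog pairs mirrored about the midline (x = 0); an odd
    count leaves one unpaired midline cell.  Each neuron is assigned to
    one of the six glial packets by its canonical position.  Deterministic
    for a fixed seed.
    """
    if n_per_surface < 2:
        raise ParameterError("n_per_surface must be >= 2")
    rng = np.random.default_rng(seed)
    neurons: list[Neuron] = []
    for surface in SURFACES:
        prefix = surface[0].upper()
        # (x, y, r) of every placed soma, mirrors included
        px_arr = np.empty(0)
        py_arr = np.empty(0)
        pr_arr = np.empty(0)
        n_pairs = n_per_surface // 2
        for k in range(n_pairs):
            # leech somata are large relative to their spacing; dense maps
            # progressively tolerate touching (sep factor decays) rather
            # than failing
            sep = 0.75
            while True:
                for _ in range(200):
                    r = float(rng.uniform(5.0, 12.0))
                    x = float(rng.uniform(r + 2.0, _X_HALF_UM * 0.95))
                    y = float(rng.uniform(-_Y_HALF_UM * 0.95,
                                          _Y_HALF_UM * 0.95))
                    if (x / _X_HALF_UM) ** 2 + (y / _Y_HALF_UM) ** 2 >= 1.0:
                        continue
                    d = np.hypot(px_arr - x, py_arr - y)
                    if np.all(d >= sep * (pr_arr + r)):
                        break
                else:  # pragma: no cover - dense layouts only
                    sep *= 0.85
                    continue
                break
            px_arr = np.r_[px_arr, x, -x]
            py_arr = np.r_[py_arr, y, y]
            pr_arr = np.r_[pr_arr, r, r]
            rid = f"{prefix}{k + 1:03d}R"
            lid = f"{prefix}{k + 1:03d}L"
            pk_r = _packet_of(x, y)
            pk_l = _packet_of(-x, y)
            neurons.append(Neuron(rid, surface, pk_r, x, y, r, lid))
            neurons.append(Neuron(lid, surface, pk_l, -x, y, r, rid))
        if n_per_surface % 2:
            r = float(rng.uniform(5.0, 12.0))
            y = float(rng.uniform(-_Y_HALF_UM * 0.6, _Y_HALF_UM * 0.6))
            neurons.append(
                Neuron(f"{prefix}000M", surface, _packet_of(0.0, y), 0.0, y, r, None)
            )
    return CanonicalMap(neurons)


# ---------------------------------------------------------------------------
# Activity programs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillationTerm:
    """One behavioral oscillation component of a cell's program."""

    amplitude_mV: float = 0.0
    frequency_Hz: float = 1.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_mV < 0:
            raise ParameterError("oscillation amplitude must be >= 0")
        if self.frequency_Hz <= 0:
            raise ParameterError("oscillation frequency must be > 0")
        if not -math.pi <= self.phase_rad < math.pi:
            raise ParameterError("phase must lie in [-pi, pi)")


@dataclass(frozen=True)
class CellProgram:
    """Membrane-potential program for one cell.

    Spikes briefer than one frame are represented by their frame-integrated
    area at render resolution; EPSPs are instant-rise exponential-decay
    events of 2-4 mV, the unitary size the optical signal resolves.
    """

    baseline_mV: float = -50.0
    swim: OscillationTerm = field(default_factory=OscillationTerm)
    crawl: OscillationTerm = field(default_factory=OscillationTerm)
    bend_left_mV: float = 0.0    # depolarization during left-P-cell trials
    bend_right_mV: float = 0.0
    spike_rate_Hz: float = 0.0
    spike_amplitude_mV: float = 40.0
    spike_width_s: float = 0.005
    epsp_rate_Hz: float = 0.0
    epsp_amplitude_mV: float = 3.0
    epsp_decay_s: float = 0.3
    noise_sd_mV: float = 0.0

    def __post_init__(self) -> None:
        for name in ("spike_rate_Hz", "spike_amplitude_mV", "spike_width_s",
                     "epsp_rate_Hz", "epsp_amplitude_mV", "epsp_decay_s",
                     "noise_sd_mV"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class ActivityProgram:
    """Per-cell programs plus the designated optical reference cell."""

    cells: dict[str, CellProgram]
    reference_id: str | None = None

    def __getitem__(self, cell_id: str) -> CellProgram:
        return self.cells[cell_id]


def default_program(
    cmap: CanonicalMap,
    behavior: str,
    seed: int,
    involved_fraction: float = 0.5,
    swim_frequency_Hz: float = 1.5,
    crawl_frequency_Hz: float = 0.2,
    noise_sd_mV: float = 1.0,
) -> ActivityProgram:
    """Assign a plausible activity program to every neuron of a map.

    For swim/crawl, a seeded subset of cells oscillates at the shared
    rhythm frequency (amplitudes 4-8 mV, random phases; homologs share
    phase).  For bend, a subset responds to left and/or right stimulation
    (0-6 mV), so some cells are differential ("encoders") and others
    symmetric.  The cell with the largest swim amplitude is designated the
    optical reference (phase 0), standing in for a DI-1 motor neuron.
    """
    rng = np.random.default_rng(seed)
    cells: dict[str, CellProgram] = {}
    done: set[str] = set()
    ref_id, ref_amp = None, -1.0
    for n in cmap.neurons:
        if n.id in done:
            continue
        group = [n.id]
        if n.homolog_id is not None:
            group.append(n.homolog_id)
        done.update(group)
        involved = rng.random() < involved_fraction
        amp = float(rng.uniform(4.0, 8.0)) if involved else 0.0
        phase = float(rng.uniform(-math.pi, math.pi))
        left = float(rng.uniform(0.0, 6.0)) if involved else 0.0
        right = float(rng.uniform(0.0, 6.0)) if involved else 0.0
        for cid in group:
            swim = OscillationTerm(amp if behavior == "swim" else 0.0,
                                   swim_frequency_Hz, phase)
            crawl = OscillationTerm(amp if behavior == "crawl" else 0.0,
                                    crawl_frequency_Hz, phase)
            cells[cid] = CellProgram(
                swim=swim,
                crawl=crawl,
                bend_left_mV=left if behavior == "bend" else 0.0,
                bend_right_mV=right if behavior == "bend" else 0.0,
                spike_rate_Hz=float(rng.uniform(0.0, 1.0)),
                epsp_rate_Hz=float(rng.uniform(0.2, 1.5)),
                epsp_amplitude_mV=float(rng.uniform(2.0, 4.0)),
                noise_sd_mV=noise_sd_mV,
            )
            if behavior in ("swim", "crawl") and amp > ref_amp:
                ref_id, ref_amp = cid, amp
    if ref_id is not None:
        # re-pin the reference cell's phase to zero (phase-0 convention)
        old = cells[ref_id]
        cells[ref_id] = CellProgram(
            baseline_mV=old.baseline_mV,
            swim=OscillationTerm(old.swim.amplitude_mV, old.swim.frequency_Hz, 0.0),
            crawl=OscillationTerm(old.crawl.amplitude_mV, old.crawl.frequency_Hz, 0.0),
            bend_left_mV=old.bend_left_mV, bend_right_mV=old.bend_right_mV,
            spike_rate_Hz=old.spike_rate_Hz,
            epsp_rate_Hz=old.epsp_rate_Hz,
            epsp_amplitude_mV=old.epsp_amplitude_mV,
            noise_sd_mV=old.noise_sd_mV,
        )
    return ActivityProgram(cells=cells, reference_id=ref_id)


# ---------------------------------------------------------------------------
# Stimulus protocol
# ---------------------------------------------------------------------------

@dataclass
class StimulusProtocol:
    """Left/right P-cell stimulation trials: 20 Hz pulse trains, 1 s, 50% duty.

    Trials come in (L,R)/(R,L) pairs — the order LRRLLRRL... — with equal
    counts of the two labels.
    """

    labels: list[str]
    onsets_s: list[float]
    duration_s: float = 1.0
    pulse_rate_Hz: float = 20.0
    duty: float = 0.5

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.onsets_s):
            raise ConsistencyError("labels and onsets differ in length")
        if any(l not in ("L", "R") for l in self.labels):
            raise ParameterError("labels must be 'L' or 'R'")
        if self.labels.count("L") != self.labels.count("R"):
            raise ParameterError("equal counts of L and R trials required")
        for i in range(0, len(self.labels) - 1, 2):
            pair = (self.labels[i], self.labels[i + 1])
            if pair not in (("L", "R"), ("R", "L")):
                raise ParameterError("consecutive pairs must be (L,R) or (R,L)")

    @property
    def n_trials(self) -> int:
        return len(self.labels)

    @classmethod
    def default(cls, n_trials: int = 20, first_onset_s: float = 2.0,
                period_s: float = 3.0) -> "StimulusProtocol":
        """(LR)(RL)(LR)(RL)... protocol; 20 trials = 10 per P cell."""
        if n_trials % 2:
            raise ParameterError("n_trials must be even")
        labels = []
        for p in range(n_trials // 2):
            labels += ["L", "R"] if p % 2 == 0 else ["R", "L"]
        onsets = [first_onset_s + period_s * i for i in range(n_trials)]
        return cls(labels=labels, onsets_s=onsets)

    def train(self, frame_times: np.ndarray) -> np.ndarray:
        """Binary on/off stimulus series at frame resolution (both labels)."""
        out = np.zeros_like(frame_times)
        for onset in self.onsets_s:
            out[(frame_times >= onset) & (frame_times < onset + self.duration_s)] = 1.0
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "labels": self.labels, "onsets_s": self.onsets_s,
            "duration_s": self.duration_s, "pulse_rate_Hz": self.pulse_rate_Hz,
            "duty": self.duty,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusProtocol":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# Voltage simulation
# ---------------------------------------------------------------------------

_BEHAVIOR_RATES = {"bend": 50.0, "swim": 50.0, "crawl": 20.0}


def simulate_voltages(
    cmap: CanonicalMap,
    program: ActivityProgram,
    behavior: str,
    protocol: StimulusProtocol | None,
    duration_s: float,
    rate_Hz: float,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-cell membrane voltage traces (mV) at frame rate.

    Each trace is baseline + behavioral oscillation or stimulus-locked
    response + spikes + EPSPs + Gaussian membrane noise.  Returns the
    voltage table (index = time in s, one column per cell) and a ground
    truth dict holding, per cell, the oscillation parameters, the phase
    relative to the designated reference cell, and the mean L-minus-R
    stimulus-window response difference.
    """
    if behavior not in _BEHAVIOR_RATES:
        raise ParameterError(f"unknown behavior {behavior!r}")
    if behavior == "bend" and protocol is None:
        raise ParameterError("behavior 'bend' requires a stimulus protocol")
    if rate_Hz != _BEHAVIOR_RATES[behavior]:
        warnings.warn(
            f"frame rate {rate_Hz} Hz is unusual for {behavior} "
            f"(typical: {_BEHAVIOR_RATES[behavior]} Hz)", stacklevel=2)
    n = int(round(duration_s * rate_Hz))
    dt = 1.0 / rate_Hz
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)

    ref_phase = 0.0
    if program.reference_id is not None:
        refterm = getattr(program[program.reference_id], behavior, None)
        if isinstance(refterm, OscillationTerm):
            ref_phase = refterm.phase_rad

    cols: dict[str, np.ndarray] = {}
    truth_cells: dict[str, dict] = {}
    for neuron in cmap.neurons:
        prog = program[neuron.id]
        v = np.full(n, prog.baseline_mV)
        osc_amp, osc_phase = 0.0, 0.0
        if behavior in ("swim", "crawl"):
            term: OscillationTerm = getattr(prog, behavior)
            osc_amp, osc_phase = term.amplitude_mV, term.phase_rad
            v = v + osc_amp * np.sin(
                2 * np.pi * term.frequency_Hz * t + osc_phase)
        lr_diff = 0.0
        if behavior == "bend":
            assert protocol is not None
            for label, onset in zip(protocol.labels, protocol.onsets_s):
                amp = prog.bend_left_mV if label == "L" else prog.bend_right_mV
                v[(t >= onset) & (t < onset + protocol.duration_s)] += amp
            lr_diff = prog.bend_left_mV - prog.bend_right_mV
        # spikes: Poisson events, frame-integrated area (undersampled at
        # frame rate, so a spike contributes amplitude*width/dt to one frame)
        if prog.spike_rate_Hz > 0:
            n_sp = rng.poisson(prog.spike_rate_Hz * duration_s)
            if n_sp:
                idx = rng.integers(0, n, n_sp)
                np.add.at(v, idx,
                          prog.spike_amplitude_mV * prog.spike_width_s / dt)
        # EPSPs: instant rise, exponential decay
        if prog.epsp_rate_Hz > 0:
            n_ep = rng.poisson(prog.epsp_rate_Hz * duration_s)
            if n_ep:
                deltas = np.zeros(n)
                np.add.at(deltas, rng.integers(0, n, n_ep),
                          prog.epsp_amplitude_mV)
                decay = math.exp(-dt / prog.epsp_decay_s)
                v = v + signal.lfilter([1.0], [1.0, -decay], deltas)
        if prog.noise_sd_mV > 0:
            v = v + rng.normal(0.0, prog.noise_sd_mV, n)
        cols[neuron.id] = v
        truth_cells[neuron.id] = {
            "osc_amplitude_mV": osc_amp,
            "osc_phase_rad": osc_phase,
            "phase_vs_reference_rad": float(
                np.angle(np.exp(1j * (osc_phase - ref_phase)))),
            "lr_difference_mV": lr_diff,
            "involved": bool(osc_amp > 0 or (behavior == "bend" and (
                prog.bend_left_mV > 0 or prog.bend_right_mV > 0))),
        }
    voltages = pd.DataFrame(cols, index=pd.Index(t, name="time_s"))
    truth = {
        "behavior": behavior,
        "rate_Hz": rate_Hz,
        "reference_id": program.reference_id,
        "cells": truth_cells,
    }
    return voltages, truth


# ---------------------------------------------------------------------------
# Imaging forward model
# ---------------------------------------------------------------------------

@dataclass
class ImagingParams:
    """Camera/optics parameters of the forward model.

    ``sensitivity`` is the relative fluorescence change per 100 mV of
    depolarization (percent; the dye reaches ~2.7%/100 mV at rest).
    ``shot_noise_ppm`` calibrates photon noise so that the frame-to-frame
    relative noise of a cell-sized area matches this many parts per
    million.  Bleaching is a single-exponential decay applied
    multiplicatively; the global fluctuation is one low-pass series shared
    by all pixels of both views — stray light from fluorescent crosstalk
    between the two images, added with amplitude ``global_sd`` of each
    view's mean brightness; motion is a slow rigid trajectory per view.
    """

    frame_shape: tuple[int, int] = (128, 512)   # (rows, cols)
    frame_rate_Hz: float = 50.0
    sensitivity: float = 2.7          # % dF/F per 100 mV
    v_rest_mV: float = -50.0
    baseline_counts: float = 100.0    # dim background level per pixel
    cell_peak_counts: float = 1500.0  # peak added counts at a cell center
    shot_noise_ppm: float = 70.0      # per cell-sized area; 0 disables
    bleach_amplitude: float = 0.05    # fraction lost as t -> inf (<= 0.1)
    bleach_tau_s: float = 30.0        # >= 10 s
    global_sd: float = 0.0            # shared stray-light sd, rel. to mean
    global_bandwidth_Hz: float = 0.5
    motion_amplitude_px: float = 0.0  # rms of per-view trajectory
    motion_bandwidth_Hz: float = 1.0
    um_per_px: float | None = None    # None: auto-fit the map to the frame

    def __post_init__(self) -> None:
        for name in ("sensitivity", "baseline_counts", "cell_peak_counts",
                     "shot_noise_ppm", "bleach_amplitude", "bleach_tau_s",
                     "global_sd", "motion_amplitude_px"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.frame_rate_Hz <= 0:
            raise ParameterError("frame_rate_Hz must be > 0")


@dataclass
class DualRecording:
    """Two synchronized stacks plus events and (synthetic-only) truth."""

    stacks: list[np.ndarray]          # [ventral, dorsal], each (T, rows, cols)
    frame_times: np.ndarray           # s, strictly increasing
    events: dict                      # protocol, reference cell id, behavior
    truth: dict | None = None

    def __post_init__(self) -> None:
        if len(self.stacks) != 2 or self.stacks[0].shape[0] != self.stacks[1].shape[0]:
            raise ConsistencyError("need two stacks of equal frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ConsistencyError("frame_times must be strictly increasing")

    @property
    def views(self) -> tuple[str, str]:
        return SURFACES

    def truth_rois(self) -> pd.DataFrame:
        """Ground-truth ROI table (id, view, center_x, center_y, radius), px."""
        if self.truth is None:
            raise ValueError("no ground truth on this recording")
        return pd.DataFrame(self.truth["rois"])


def _resolve_um_per_px(cmap: CanonicalMap, params: ImagingParams) -> float:
    """Pixel pitch; auto-fitted so every cell plus margin lands in frame."""
    if params.um_per_px is not None:
        return params.um_per_px
    rows, cols = params.frame_shape
    need = 1e-6
    for n in cmap.neurons:
        need = max(need,
                   (abs(n.x) + 3 * n.radius) / max(cols / 2.0 - 2.0, 1.0),
                   (abs(n.y) + 3 * n.radius) / max(rows / 2.0 - 2.0, 1.0))
    return need


def _cell_pixel_position(neuron: Neuron, params: ImagingParams,
                         um_per_px: float) -> tuple[float, float]:
    """Canonical um coordinates -> pixel coordinates in that neuron's view.

    The dorsal camera faces the opposite side, so the dorsal view is
    rendered left-right mirrored relative to canonical coordinates.
    """
    rows, cols = params.frame_shape
    px = neuron.x / um_per_px + cols / 2.0
    py = neuron.y / um_per_px + rows / 2.0
    if neuron.surface == "dorsal":
        px = (cols - 1.0) - px
    return px, py


def _lowpass_series(rng: np.random.Generator, n: int, fs: float,
                    bandwidth_Hz: float, sd: float) -> np.ndarray:
    """Zero-mean low-pass Gaussian series with the requested sd."""
    x = rng.normal(0.0, 1.0, n)
    nyq = fs / 2.0
    wc = min(bandwidth_Hz / nyq, 0.99)
    if wc > 0 and n > 12:
        b, a = signal.butter(2, wc)
        x = signal.filtfilt(b, a, x)
    x -= x.mean()
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def render_recording(
    cmap: CanonicalMap,
    voltages: pd.DataFrame,
    params: ImagingParams,
    seed: int,
    truth: dict | None = None,
) -> DualRecording:
    """Render voltage traces into a dual-view image recording.

    Each cell is a 2-D Gaussian intensity profile (sigma = radius/2) on a
    dim background.  Pixel values follow the linear forward model
    ``F0 * (1 + sensitivity * (V - v_rest) / 100 mV)`` multiplied by the
    bleach and global-fluctuation series, then rigid per-view motion is
    applied by sub-pixel bilinear resampling and Poisson-like noise scaled
    to ``shot_noise_ppm`` is added.  The imposed motion trajectories, the
    exact forward-model percent dF/F per cell, and pixel-space ROI centers
    are stored in the recording's ground truth.
    """
    n_frames = len(voltages)
    t = voltages.index.to_numpy(dtype=float)
    if n_frames == 0:
        raise ConsistencyError("empty voltage table")
    rows, cols = params.frame_shape
    rng = np.random.default_rng(seed)

    bleach = (1.0 - params.bleach_amplitude
              + params.bleach_amplitude * np.exp(-t / params.bleach_tau_s))
    # shared crosstalk series (unit sd, same for both views); added as
    # stray light, scaled per view to global_sd of that view's brightness
    glob_z = _lowpass_series(rng, n_frames, params.frame_rate_Hz,
                             params.global_bandwidth_Hz, 1.0) \
        if params.global_sd > 0 else np.zeros(n_frames)

    missing = [n.id for n in cmap.neurons if n.id not in voltages.columns]
    if missing:
        raise ConsistencyError(f"voltage traces missing for cells: {missing[:5]}")
    um_per_px = _resolve_um_per_px(cmap, params)

    stacks: list[np.ndarray] = []
    trajectories: dict[str, dict[str, list[float]]] = {}
    roi_truth: list[dict] = []
    dff_truth: dict[str, np.ndarray] = {}
    for view in SURFACES:
        # per-view rigid trajectory; applied by displacing the analytic
        # cell profiles themselves, so sub-pixel motion carries no
        # resampling artifact (real motion moves light, it does not blur)
        dx = _lowpass_series(rng, n_frames, params.frame_rate_Hz,
                             params.motion_bandwidth_Hz,
                             params.motion_amplitude_px)
        dy = _lowpass_series(rng, n_frames, params.frame_rate_Hz,
                             params.motion_bandwidth_Hz,
                             params.motion_amplitude_px)
        margin = int(math.ceil(np.abs(np.r_[dx, dy, 0.0]).max())) + 1
        base = np.full((n_frames, rows, cols), params.baseline_counts)
        cell_fluxes: list[float] = []
        for neuron in [n for n in cmap.neurons if n.surface == view]:
            v = voltages[neuron.id].to_numpy(dtype=float)
            gain = 1.0 + params.sensitivity * (v - params.v_rest_mV) / 100.0 / 100.0
            # sensitivity is in percent per 100 mV, hence the second /100
            px, py = _cell_pixel_position(neuron, params, um_per_px)
            sig = max(neuron.radius / um_per_px / 2.0, 0.8)
            half = int(math.ceil(4 * sig)) + margin
            x0, x1 = max(0, int(px) - half), min(cols, int(px) + half + 1)
            y0, y1 = max(0, int(py) - half), min(rows, int(py) + half + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            # positive dx = rightward content shift (0-based, x = column)
            gx = np.exp(-(xs[None, :] - px - dx[:, None]) ** 2 / (2 * sig ** 2))
            gy = np.exp(-(ys[None, :] - py - dy[:, None]) ** 2 / (2 * sig ** 2))
            patch_t = params.cell_peak_counts * np.einsum("th,tw->thw", gy, gx)
            base[:, y0:y1, x0:x1] += gain[:, None, None] * patch_t
            cell_fluxes.append(params.cell_peak_counts
                               * 2.0 * math.pi * sig ** 2)
            roi_truth.append({
                "id": neuron.id, "view": view, "center_x": px, "center_y": py,
                "radius": neuron.radius / um_per_px,
            })
            dff_truth[neuron.id] = params.sensitivity * (v - params.v_rest_mV) / 100.0
        stack = base * bleach[:, None, None]
        if params.global_sd > 0:
            # fluorescent crosstalk between the two images adds stray
            # light uniformly; an additive shared offset is what per-frame
            # non-ROI background subtraction removes
            amp = params.global_sd * float(base[0].mean())
            stack = stack + (amp * glob_z)[:, None, None]
        if params.shot_noise_ppm > 0:
            # Poisson-like noise: per-pixel variance proportional to
            # intensity, with the gain calibrated so that the mean over a
            # typical cell footprint has the requested relative ppm noise.
            flux = np.median(cell_fluxes) if cell_fluxes else (
                params.baseline_counts * 100.0)
            area_bg = 0.0
            if cell_fluxes:
                sig_med = np.median(
                    [r["radius"] / 2.0 for r in roi_truth if r["view"] == view])
                area_bg = math.pi * (2 * sig_med) ** 2 * params.baseline_counts
            target_rel = params.shot_noise_ppm * 1e-6
            gain_e = target_rel ** 2 * (flux + area_bg)
            stack = stack + rng.normal(0.0, 1.0, stack.shape) * np.sqrt(
                gain_e * np.clip(stack, 0.0, None))
        stacks.append(stack)
        trajectories[view] = {"dx_px": dx.tolist(), "dy_px": dy.tolist()}

    full_truth = {
        "motion": trajectories,
        "rois": roi_truth,
        "dff_percent": {k: v.tolist() for k, v in dff_truth.items()},
    }
    if truth:
        full_truth.update(truth)
    events = {
        "behavior": (truth or {}).get("behavior"),
        "reference_id": (truth or {}).get("reference_id"),
    }
    return DualRecording(stacks=stacks, frame_times=t, events=events,
                         truth=full_truth)


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def write_recording(rec: DualRecording, outdir: str | Path) -> dict[str, Path]:
    """Write stacks as multi-page TIFF (one per view), truth/events as JSON,
    ROI ground truth as CSV.  Returns the paths written."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for view, stack in zip(rec.views, rec.stacks):
        p = outdir / f"stack_{view}.tiff"
        tifffile.imwrite(p, stack.astype(np.float32))
        paths[f"stack_{view}"] = p
    p = outdir / "events.json"
    p.write_text(json.dumps({
        "frame_times_s": rec.frame_times.tolist(), **rec.events}, indent=1))
    paths["events"] = p
    if rec.truth is not None:
        p = outdir / "truth.json"
        p.write_text(json.dumps(rec.truth))
        paths["truth"] = p
        p = outdir / "rois_truth.csv"
        rec.truth_rois().to_csv(p, index=False)
        paths["rois"] = p
    return paths
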