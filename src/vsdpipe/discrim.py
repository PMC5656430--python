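"""Stimulus-identity decoding by partner-excluding leave-one-out prediction.

During fictive local bending, left and right ventral P cells are
stimulated in alternating pairs — the order (LR)(RL)(LR)(RL)... — for 10
trials per side.  Each cell's single-trial response is the average
percent dF/F during the first 0.5 s of the stimulus (and, as a control,
during 1-0.5 s before onset), both taken relative to a reference phase
0.5-0.1 s before onset.

Decoding uses a nearest-class-mean rule with a paired exclusion: for each
held-out trial, that trial *and its partner* (the next trial for
odd-numbered trials, the preceding trial for even-numbered ones — i.e.
the other member of its L/R pair) are removed, class means are computed
from the remaining trials, and the held-out response is assigned to the
nearer class mean.  The fraction of correctly predicted trials is the
cell's prediction success; 50% is chance, and cells at or above 75% are
considered to encode stimulus identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import StimulusProtocol

__all__ = [
    "TrialResponse",
    "PredictionScore",
    "window_responses",
    "partner_index",
    "loo_prediction_success",
    "loo_success_batch",
    "score_cells",
    "discriminability_map",
    "ENCODER_THRESHOLD",
]

ENCODER_THRESHOLD = 0.75

# response windows relative to stimulus onset, seconds
STIM_WINDOW = (0.0, 0.5)
CONTROL_WINDOW = (-1.0, -0.5)
REFERENCE_WINDOW = (-0.5, -0.1)


class ProtocolError(ValueError):
    """The trial structure violates the paired-protocol assumptions."""


@dataclass
class TrialResponse:
    """One cell's responses for one trial (percent dF/F, reference-relative)."""

    cell_id: str
    trial_index: int  # 1-based
    label: str        # "L" | "R"
    stim_response: float
    control_response: float


@dataclass
class PredictionScore:
    """Leave-one-out prediction success of one cell in one phase."""

    cell_id: str
    phase: str              # "stimulus" | "control"
    success_fraction: float
    n_trials: int
    encoder: bool           # success >= 75%


def _window_mean(values: np.ndarray, times: np.ndarray,
                 onset: float, window: tuple[float, float]) -> float:
    lo, hi = onset + window[0], onset + window[1]
    if lo < times[0] - 1e-9 or hi > times[-1] + (times[1] - times[0]) + 1e-9:
        raise ValueError(f"response window [{lo:.2f}, {hi:.2f}] s is outside "
                         "the recording")
    sel = (times >= lo) & (times < hi)
    if not sel.any():
        raise ValueError("empty response window")
    return float(values[sel].mean())


def window_responses(traces: pd.DataFrame, protocol: StimulusProtocol,
                     frame_times: np.ndarray | None = None) -> pd.DataFrame:
    """Per-trial stimulus and control responses for every cell.

    ``traces`` has one column per cell (percent dF/F), indexed by frame
    time in seconds unless ``frame_times`` is given.  Both responses are
    window means relative to the mean of the reference phase.
    """
    times = (traces.index.to_numpy(dtype=float) if frame_times is None
             else np.asarray(frame_times, dtype=float))
    rows = []
    for cid in traces.columns:
        v = traces[cid].to_numpy(dtype=float)
        for i, (label, onset) in enumerate(zip(protocol.labels,
                                               protocol.onsets_s), start=1):
            ref = _window_mean(v, times, onset, REFERENCE_WINDOW)
            rows.append(TrialResponse(
                cell_id=str(cid), trial_index=i, label=label,
                stim_response=_window_mean(v, times, onset, STIM_WINDOW) - ref,
                control_response=_window_mean(v, times, onset, CONTROL_WINDOW) - ref,
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


def partner_index(trial_index: int, n_trials: int) -> int:
    """Partner of a 1-based trial: next for odd trials, preceding for even.

    Partnership is an involution pairing the trials into their (L,R)/(R,L)
    stimulus pairs.
    """
    if n_trials % 2:
        raise ProtocolError("n_trials must be even")
    if not 1 <= trial_index <= n_trials:
        raise ValueError("trial_index out of range")
    return trial_index + 1 if trial_index % 2 else trial_index - 1


def loo_prediction_success(responses: np.ndarray, labels: np.ndarray,
                           cell_id: str = "", phase: str = "stimulus",
                           threshold: float = ENCODER_THRESHOLD,
                           ) -> PredictionScore:
    """Partner-excluding leave-one-out nearest-class-mean success.

    For each trial, that trial and its partner are removed, the mean
    response of each remaining class is computed, and the held-out
    response is predicted as the class with the nearer mean (exact ties
    count as incorrect).  Returns the fraction of correct predictions.
    """
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    n = len(responses)
    if len(labels) != n:
        raise ValueError("responses and labels differ in length")
    is_l = labels == "L"
    n_l = int(is_l.sum())
    if n_l * 2 != n:
        raise ProtocolError("equal L and R trial counts required")
    if n_l < 2:
        raise ProtocolError("need at least 2 trials per class")
    correct = 0
    for i in range(1, n + 1):
        j = partner_index(i, n)
        keep = np.ones(n, dtype=bool)
        keep[[i - 1, j - 1]] = False
        mean_l = responses[keep & is_l].mean()
        mean_r = responses[keep & ~is_l].mean()
        r = responses[i - 1]
        d_l, d_r = abs(r - mean_l), abs(r - mean_r)
        if d_l == d_r:
            continue  # tie: conservative, scored incorrect
        pred = "L" if d_l < d_r else "R"
        correct += pred == labels[i - 1]
    frac = correct / n
    return PredictionScore(cell_id=cell_id, phase=phase,
                           success_fraction=frac, n_trials=n,
                           encoder=frac >= threshold)


def loo_success_batch(responses: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized success fractions for many cells at once.

    ``responses`` is (n_cells, n_trials); all cells share the label
    sequence.  Exploits the pairing structure: removing a trial and its
    partner removes exactly one trial from each class, so the
    leave-pair-out class means are running sums minus one element.
    """
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    m, n = responses.shape
    is_l = labels == "L"
    if int(is_l.sum()) * 2 != n:
        raise ProtocolError("equal L and R trial counts required")
    n_cl = n // 2
    partner = np.array([partner_index(i, n) - 1 for i in range(1, n + 1)])
    held = responses                                   # (m, n)
    removed_l = np.where(is_l, responses, responses[:, partner])
    removed_r = np.where(is_l, responses[:, partner], responses)
    sum_l = responses[:, is_l].sum(axis=1, keepdims=True)
    sum_r = responses[:, ~is_l].sum(axis=1, keepdims=True)
    mean_l = (sum_l - removed_l) / (n_cl - 1)
    mean_r = (sum_r - removed_r) / (n_cl - 1)
    d_l = np.abs(held - mean_l)
    d_r = np.abs(held - mean_r)
    pred_l = d_l < d_r
    pred_r = d_r < d_l
    correct = np.where(is_l, pred_l, pred_r)           # ties incorrect
    return correct.mean(axis=1)


def score_cells(responses: pd.DataFrame, threshold: float = ENCODER_THRESHOLD
                ) -> pd.DataFrame:
    """Prediction scores for every cell and phase from a response table."""
    rows = []
    for cid, grp in responses.groupby("cell_id"):
        grp = grp.sort_values("trial_index")
        labels = grp["label"].to_numpy()
        for phase, col in (("stimulus", "stim_response"),
                           ("control", "control_response")):
            s = loo_prediction_success(grp[col].to_numpy(), labels,
                                       cell_id=str(cid), phase=phase,
                                       threshold=threshold)
            rows.append(s.__dict__)
    return pd.DataFrame(rows)


def discriminability_map(scores: pd.DataFrame, assignment=None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scores keyed by identified neuron, plus encoder counts vs control.

    ``assignment`` maps ROI ids to neuron ids (an AssignmentMap from the
    cartography module, or any mapping); cells without an assignment are
    kept in the table with a null neuron id rather than dropped.  Returns
    (table, counts) where counts has encoder totals per phase.
    """
    roi_to_neuron: dict[str, str] = {}
    if assignment is not None:
        pairs = getattr(assignment, "pairs", assignment)
        if isinstance(pairs, pd.DataFrame):
            roi_to_neuron = dict(zip(pairs["roi_id"].astype(str),
                                     pairs["neuron_id"].astype(str)))
        else:
            roi_to_neuron = {str(k): str(v) for k, v in dict(pairs).items()}
    wide = scores.pivot_table(index="cell_id", columns="phase",
                              values="success_fraction", aggfunc="first")
    wide = wide.rename(columns={"stimulus": "stimulus_success",
                                "control": "control_success"})
    wide["neuron_id"] = [roi_to_neuron.get(str(c)) for c in wide.index]
    thr = ENCODER_THRESHOLD
    counts = pd.DataFrame({
        "phase": ["stimulus", "control"],
        "encoders": [
            int((wide.get("stimulus_success", pd.Series(dtype=float)) >= thr).sum()),
            int((wide.get("control_success", pd.Series(dtype=float)) >= thr).sum()),
        ],
        "n_cells": [len(wide)] * 2,
    })
    return wide.reset_index(), counts
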