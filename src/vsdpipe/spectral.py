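"""Multitaper coherence and cross-animal involvement maps.

Each cell's optical signal is tested for coherence with a behavioral
reference (the stimulus train for local bending, the optical signal of a
reference motor neuron for swimming, an intracellular trace for
crawling), evaluated at the frequency with the greatest spectral power in
the rhythm.  Slepian (DPSS) tapers give K nearly independent spectral
estimates; under the null hypothesis that a signal is not coherent with
the reference, the coherence magnitude estimated with K tapers exceeds

    C_alpha = sqrt(1 - alpha**(1/(K-1)))

with probability ``alpha``, which is the analytic 1-alpha confidence
bound used to call a cell involved in a behavior.  A cell is considered
consistently involved if it exceeds the 95% bound in at least four of six
animals; for the bilaterally symmetric behaviors (swimming, crawling)
both members of a homolog pair are included if at least one member
exceeds the 97.5% bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

__all__ = [
    "CoherenceResult",
    "pick_rhythm_frequency",
    "multitaper_coherence",
    "coherence_table",
    "null_threshold",
    "simulate_null_magnitudes",
    "InvolvementMap",
    "involvement",
]

SYMMETRIC_BEHAVIORS = frozenset({"swim", "crawl"})


@dataclass
class CoherenceResult:
    """Coherence of one cell with the reference at one frequency."""

    cell_id: str
    frequency_Hz: float
    magnitude: float            # in [0, 1]
    phase_rad: float            # in [-pi, pi); positive = cell leads reference
    magnitude_ci: tuple[float, float]
    null_threshold: float
    involved: bool


def _check_taper_params(n: int, nw: float, k_tapers: int) -> None:
    if k_tapers < 2:
        raise ValueError("k_tapers must be >= 2")
    if k_tapers >= 2 * nw:
        raise ValueError("k_tapers must be < 2*NW for well-behaved tapers")
    if n < k_tapers + 1:
        raise ValueError("series too short for the requested tapers")


def _tapered_ffts(x: np.ndarray, nw: float, k_tapers: int) -> np.ndarray:
    """DPSS-tapered FFTs; x is (..., n), result (..., K, n_freq)."""
    n = x.shape[-1]
    tapers = dpss(n, nw, Kmax=k_tapers)          # (K, n)
    return rfft(x[..., None, :] * tapers, axis=-1)


def pick_rhythm_frequency(series: np.ndarray, fs: float,
                          band_Hz: tuple[float, float],
                          nw: float = 3.0, k_tapers: int = 5) -> float:
    """Frequency of maximum multitaper power of the reference within a band."""
    series = np.asarray(series, dtype=float)
    lo, hi = band_Hz
    if not 0 <= lo < hi or hi > fs / 2:
        raise ValueError("band must satisfy 0 <= lo < hi <= Nyquist")
    _check_taper_params(len(series), nw, k_tapers)
    X = _tapered_ffts(series - series.mean(), nw, k_tapers)
    power = (np.abs(X) ** 2).sum(axis=0)
    freqs = rfftfreq(len(series), 1.0 / fs)
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError("no frequency bins inside the requested band")
    return float(freqs[in_band][np.argmax(power[in_band])])


def null_threshold(k_tapers: int, alpha: float = 0.05) -> float:
    """Magnitude bound exceeded with probability ``alpha`` under the null.

    Closed form ``sqrt(1 - alpha**(1/(K-1)))`` for a coherence magnitude
    estimated from K independent tapers of incoherent signals.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k_tapers < 2:
        raise ValueError("k_tapers must be >= 2")
    return float(np.sqrt(1.0 - alpha ** (1.0 / (k_tapers - 1))))


def _coherence_at_bin(X: np.ndarray, Y: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coherency from per-taper spectra at one bin.

    X, Y are (..., K) complex.  Returns (magnitude, phase, per-taper
    leave-one-out magnitudes for jackknife CIs).
    """
    sxy = (X * np.conj(Y)).sum(axis=-1)
    sxx = (np.abs(X) ** 2).sum(axis=-1)
    syy = (np.abs(Y) ** 2).sum(axis=-1)
    coh = sxy / np.sqrt(sxx * syy)
    k = X.shape[-1]
    # leave-one-taper-out magnitudes
    sxy_l = sxy[..., None] - X * np.conj(Y)
    sxx_l = sxx[..., None] - np.abs(X) ** 2
    syy_l = syy[..., None] - np.abs(Y) ** 2
    mag_l = np.abs(sxy_l) / np.sqrt(sxx_l * syy_l)
    return np.abs(coh), np.angle(coh), mag_l


def multitaper_coherence(trace: np.ndarray, reference: np.ndarray, fs: float,
                         frequency: float, nw: float = 3.0, k_tapers: int = 5,
                         alpha: float = 0.05, cell_id: str = "",
                         ) -> CoherenceResult:
    """Multitaper coherence of one trace with the reference at a frequency.

    Magnitude and phase come from Slepian-tapered cross/auto spectra at the
    FFT bin nearest ``frequency``; the sign convention is positive phase =
    trace leads reference.  The magnitude CI is a jackknife over tapers on
    the arctanh scale; ``involved`` is magnitude > the analytic null bound
    at ``alpha``.
    """
    trace = np.asarray(trace, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if trace.shape != reference.shape:
        raise ValueError("trace and reference must have equal length")
    _check_taper_params(len(trace), nw, k_tapers)
    X = _tapered_ffts(trace - trace.mean(), nw, k_tapers)
    Y = _tapered_ffts(reference - reference.mean(), nw, k_tapers)
    freqs = rfftfreq(len(trace), 1.0 / fs)
    b = int(np.argmin(np.abs(freqs - frequency)))
    mag, phase, mag_l = _coherence_at_bin(X[:, b], Y[:, b])
    mag = float(mag)
    z_l = np.arctanh(np.clip(mag_l, 0.0, 1.0 - 1e-12))
    k = k_tapers
    se = np.sqrt((k - 1) / k * ((z_l - z_l.mean()) ** 2).sum())
    z = np.arctanh(min(mag, 1.0 - 1e-12))
    ci = (float(np.tanh(z - 1.96 * se)), float(min(np.tanh(z + 1.96 * se), 1.0)))
    thr = null_threshold(k_tapers, alpha)
    return CoherenceResult(
        cell_id=cell_id, frequency_Hz=float(freqs[b]), magnitude=mag,
        phase_rad=float(np.angle(np.exp(1j * phase))),
        magnitude_ci=ci, null_threshold=thr, involved=bool(mag > thr))


def coherence_table(traces: pd.DataFrame, reference: np.ndarray, fs: float,
                    frequency: float | None = None,
                    band_Hz: tuple[float, float] | None = None,
                    nw: float = 3.0, k_tapers: int = 5, alpha: float = 0.05,
                    ) -> pd.DataFrame:
    """Coherence of every column of ``traces`` with one reference.

    If ``frequency`` is omitted, it is picked as the reference's spectral
    peak within ``band_Hz``.  Returns one row per cell: cell_id, freq_hz,
    magnitude, phase_rad, ci_lo, ci_hi, threshold, involved.
    """
    reference = np.asarray(reference, dtype=float)
    if frequency is None:
        if band_Hz is None:
            raise ValueError("give either frequency or band_Hz")
        frequency = pick_rhythm_frequency(reference, fs, band_Hz, nw, k_tapers)
    rows = []
    for cid in traces.columns:
        r = multitaper_coherence(traces[cid].to_numpy(), reference, fs,
                                 frequency, nw, k_tapers, alpha, cell_id=str(cid))
        rows.append({"cell_id": r.cell_id, "freq_hz": r.frequency_Hz,
                     "magnitude": r.magnitude, "phase_rad": r.phase_rad,
                     "ci_lo": r.magnitude_ci[0], "ci_hi": r.magnitude_ci[1],
                     "threshold": r.null_threshold, "involved": r.involved})
    return pd.DataFrame(rows)


def simulate_null_magnitudes(n_samples: int, n_pairs: int, seed: int,
                             nw: float = 3.0, k_tapers: int = 5,
                             frequency_bin: int | None = None,
                             chunk: int = 1000) -> np.ndarray:
    """Coherence magnitudes of independent white-noise pairs (vectorized).

    Used to validate the analytic null threshold by Monte Carlo: the
    fraction of magnitudes above ``null_threshold(k, alpha)`` should equal
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    if frequency_bin is None:
        frequency_bin = n_samples // 8  # interior bin, away from DC/Nyquist
    tapers = dpss(n_samples, nw, Kmax=k_tapers)
    out = np.empty(n_pairs)
    done = 0
    while done < n_pairs:
        m = min(chunk, n_pairs - done)
        x = rng.standard_normal((m, n_samples))
        y = rng.standard_normal((m, n_samples))
        X = rfft(x[:, None, :] * tapers, axis=-1)[..., frequency_bin]
        Y = rfft(y[:, None, :] * tapers, axis=-1)[..., frequency_bin]
        mag, _, _ = _coherence_at_bin(X, Y)
        out[done:done + m] = mag
        done += m
    return out


# ---------------------------------------------------------------------------
# Cross-animal involvement
# ---------------------------------------------------------------------------

@dataclass
class InvolvementMap:
    """Per-neuron involvement booleans and Venn tabulation.

    ``table`` is indexed by neuron id with one boolean column per behavior
    plus ``determined``; ``venn`` counts neurons per combination region
    (keys like "swim", "bend+swim", "none") over the determined neurons.
    """

    table: pd.DataFrame
    venn: dict[str, int]
    behaviors: tuple[str, ...]

    @property
    def undetermined(self) -> list[str]:
        return self.table.index[~self.table["determined"]].tolist()


def involvement(per_animal_results: list[pd.DataFrame],
                homologs: dict[str, str] | None = None,
                min_animals: int = 4,
                pair_alpha_col: str = "threshold_975",
                ) -> InvolvementMap:
    """Combine per-animal coherence results into an involvement map.

    Each element of ``per_animal_results`` is one animal's table with
    columns ``neuron_id``, ``behavior``, ``magnitude``, ``threshold_95``
    and ``threshold_975``.  A neuron is involved in a behavior if its
    magnitude exceeds the 95% bound in at least ``min_animals`` animals.
    For symmetric behaviors (swim, crawl) the unit is the homolog pair: it
    counts as exceeding in an animal iff at least one member exceeds the
    97.5% bound, and an involved pair marks both members involved.
    Neurons observed in fewer than ``min_animals`` animals for some
    behavior are flagged undetermined and excluded from the Venn counts.
    """
    n_animals = len(per_animal_results)
    if min_animals > n_animals:
        raise ValueError("min_animals cannot exceed the number of animals")
    homologs = homologs or {}
    frames = []
    for a, df in enumerate(per_animal_results):
        d = df.copy()
        d["animal"] = a
        frames.append(d)
    allres = pd.concat(frames, ignore_index=True)
    behaviors = tuple(sorted(allres["behavior"].unique()))
    neurons = sorted(allres["neuron_id"].unique())

    exceeded: dict[tuple[str, str], int] = {}
    observed: dict[tuple[str, str], int] = {}
    for (nid, beh), grp in allres.groupby(["neuron_id", "behavior"]):
        observed[(nid, beh)] = grp["animal"].nunique()
        exceeded[(nid, beh)] = int((grp["magnitude"] > grp["threshold_95"]).sum())

    # pair-level exceedance at 97.5% for symmetric behaviors
    pair_exceeded: dict[tuple[frozenset, str], int] = {}
    for beh in behaviors:
        if beh not in SYMMETRIC_BEHAVIORS:
            continue
        sub = allres[allres["behavior"] == beh]
        for a, grp in sub.groupby("animal"):
            hits = set(grp.loc[grp["magnitude"] > grp[pair_alpha_col],
                               "neuron_id"])
            pairs_done = set()
            for nid in grp["neuron_id"]:
                members = frozenset({nid, homologs.get(nid, nid)})
                if members in pairs_done:
                    continue
                pairs_done.add(members)
                if members & hits:
                    key = (members, beh)
                    pair_exceeded[key] = pair_exceeded.get(key, 0) + 1

    rows = {}
    for nid in neurons:
        row = {}
        determined = True
        for beh in behaviors:
            n_obs = observed.get((nid, beh), 0)
            if n_obs < min_animals:
                row[beh] = False
                determined = False
                continue
            if beh in SYMMETRIC_BEHAVIORS:
                members = frozenset({nid, homologs.get(nid, nid)})
                row[beh] = pair_exceeded.get((members, beh), 0) >= min_animals
            else:
                row[beh] = exceeded.get((nid, beh), 0) >= min_animals
        row["determined"] = determined
        rows[nid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "neuron_id"

    venn: dict[str, int] = {}
    det = table[table["determined"]]
    for nid, row in det.iterrows():
        involved_in = [b for b in behaviors if row[b]]
        key = "+".join(involved_in) if involved_in else "none"
        venn[key] = venn.get(key, 0) + 1
    return InvolvementMap(table=table, venn=venn, behaviors=behaviors)
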