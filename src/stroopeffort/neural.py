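"""Synthetic electrophysiology from belief trajectories.

Belief updating has a dual reading as neuronal dynamics: the probability a
population assigns to its preferred state is treated as a normalised firing
rate.  Spike rasters are obtained by sampling each time bin as a Bernoulli
draw with that probability (each unit replicated across notional repeats of
the experiment); local field potentials are the rates of change of the
firing rates with the highest frequencies suppressed (Gaussian smoothing,
which is symmetric and so introduces no phase distortion); evoked responses
are condition-averaged LFPs time-locked to stimulus presentations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behaviour import SessionRecord, SessionTrace

__all__ = ["RasterSet", "LfpTraces", "sample_raster", "compute_lfp",
           "evoked_average", "session_evoked"]

DEFAULT_REPLICATIONS = 16
DEFAULT_SMOOTHING_BINS = 2.0


@dataclass
class RasterSet:
    """Binary spike indicators, shape ``(n_units, n_replications, n_bins)``."""

    spikes: np.ndarray
    unit_labels: list[tuple[str, str, int]]
    n_replications: int

    def empirical_rate(self) -> np.ndarray:
        """Mean spike rate per unit and bin across replications."""
        return self.spikes.mean(axis=1)


@dataclass
class LfpTraces:
    """Filtered rate-of-change traces, shape ``(n_units, n_bins)``."""

    traces: np.ndarray
    unit_labels: list[tuple[str, str, int]]
    smoothing_bins: float


def sample_raster(trace: SessionTrace, n_replications: int = DEFAULT_REPLICATIONS,
                  rng: np.random.Generator | None = None) -> RasterSet:
    """Sample spikes from the encoded posterior probabilities.

    Each unit's spike in each bin is an independent Bernoulli draw with
    probability equal to the belief it encodes.
    """
    if n_replications < 1:
        raise ValueError("need at least one replication")
    rng = rng or np.random.default_rng()
    p = trace.probs[:, None, :]
    spikes = (rng.random((p.shape[0], n_replications, p.shape[2])) < p)
    return RasterSet(spikes=spikes.astype(np.uint8),
                     unit_labels=list(trace.unit_labels),
                     n_replications=n_replications)


def compute_lfp(trace: SessionTrace,
                smoothing_bins: float = DEFAULT_SMOOTHING_BINS) -> LfpTraces:
    """Local field potentials: smoothed derivative of the firing rates.

    Constant beliefs give an identically zero trace.  Requires an
    iteration-resolved archive (more than one bin).
    """
    if trace.probs.shape[1] < 2:
        raise ValueError("belief archive lacks iteration resolution")
    d = np.gradient(trace.probs, axis=1)
    if smoothing_bins > 0:
        d = gaussian_filter1d(d, sigma=smoothing_bins, axis=1)
    return LfpTraces(traces=d, unit_labels=list(trace.unit_labels),
                     smoothing_bins=float(smoothing_bins))


def evoked_average(lfps: Sequence[np.ndarray],
                   labels: Sequence[str]) -> dict[str, np.ndarray]:
    """Time-locked mean LFP per label over equal-length trial epochs."""
    if len(lfps) != len(labels):
        raise ValueError("one label per trial trace required")
    if len(lfps) == 0:
        raise ValueError("no trials to average")
    lengths = {np.asarray(x).shape[-1] for x in lfps}
    if len(lengths) != 1:
        raise ValueError("trial traces must have equal length")
    out: dict[str, list[np.ndarray]] = {}
    for x, lab in zip(lfps, labels):
        out.setdefault(str(lab), []).append(np.asarray(x, float))
    return {lab: np.mean(np.stack(v), axis=0) for lab, v in out.items()}


def session_evoked(record: SessionRecord, level: str = "slow",
                   factor: str = "modality",
                   label_by: str = "congruent",
                   smoothing_bins: float = DEFAULT_SMOOTHING_BINS,
                   ) -> dict[str, np.ndarray]:
    """Condition-averaged evoked responses for one simulated session.

    Defaults select the second-level populations representing the response
    modality and group stimulus presentations by congruency
    (``label_by='correct'`` groups by response correctness instead).
    Returns label -> mean multi-unit trace ``(n_units, n_bins)``.
    """
    if record.trace is None:
        raise ValueError("session was simulated without a belief trace")
    lfp = compute_lfp(record.trace, smoothing_bins=smoothing_bins)
    units = record.trace.unit_index(level, factor)
    if units.size == 0:
        raise ValueError(f"no units for ({level}, {factor})")
    stim = record.data[record.data["phase"] == "stimulus"]
    traces, labels = [], []
    for (_, row), (b0, b1) in zip(stim.iterrows(), record.trace.trial_windows):
        traces.append(lfp.traces[np.ix_(units, np.arange(b0, b1))])
        labels.append(str(bool(row[label_by])))
    return evoked_average(traces, labels)


def evoked_amplitude(trace: np.ndarray) -> float:
    """Amplitude metric: maximum absolute deflection within the epoch."""
    return float(np.max(np.abs(trace)))


def raster_to_tsv(raster: RasterSet, path: str | Path) -> None:
    """Long TSV: unit, replication, bin, value (spikes only, for size)."""
    lines = ["unit\treplication\tbin\tvalue"]
    units, reps, bins = np.nonzero(raster.spikes)
    for u, r, b in zip(units, reps, bins):
        lines.append(f"{u}\t{r}\t{b}\t1")
    Path(path).write_text("\n".join(lines) + "\n")


def lfp_to_tsv(lfp: LfpTraces, path: str | Path) -> None:
    lines = ["unit\tbin\tvalue"]
    for u in range(lfp.traces.shape[0]):
        for b in range(lfp.traces.shape[1]):
            lines.append(f"{u}\t{b}\t{lfp.traces[u, b]:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def archive_to_hdf5(record: SessionRecord, raster: RasterSet, lfp: LfpTraces,
                    path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["condition"] = record.condition
        g = h5.create_group("units")
        g.create_dataset("labels", data=np.array(
            [f"{lv}/{f}/{s}" for lv, f, s in raster.unit_labels], dtype="S"))
        h5.create_dataset("spikes", data=raster.spikes, compression="gzip")
        h5.create_dataset("lfp", data=lfp.traces, compression="gzip")
        h5.create_dataset("beliefs", data=record.trace.probs, compression="gzip")
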