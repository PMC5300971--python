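"""Event-table I/O, intensity transforms, and NK pre-gating.

The NK gate reproduces the standard dump-channel strategy for NK cells:
keep viable CD3-CD14-CD19- events that fall in one of the three marker
quadrants CD56+CD16+, CD56+CD16- or CD56-CD16+; CD56-CD16- events (and
anything dump-positive or dead) are excluded before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._fcs import FCSError, read_fcs, write_fcs

logger = logging.getLogger(__name__)

NK_MARKERS = ("CD56", "CD16", "NKG2A", "NKG2C", "CD57")
DUMP_MARKERS = ("CD3", "CD14", "CD19")
VIABILITY_MARKER = "LiveDead"


class MissingChannelError(KeyError):
    """An input table lacks required channels; carries their names."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"missing required channels: {', '.join(self.missing)}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"missing required channels: {', '.join(self.missing)}"


@dataclass(frozen=True)
class MarkerPanel:
    """The five NK maturation markers plus dump/viability channels."""

    nk_markers: tuple[str, ...] = NK_MARKERS
    dump_markers: tuple[str, ...] = DUMP_MARKERS
    viability_marker: str = VIABILITY_MARKER

    def __post_init__(self) -> None:
        if len(self.nk_markers) != 5:
            raise ValueError("a panel needs exactly 5 NK markers")
        all_names = self.all_channels
        if len(set(all_names)) != len(all_names):
            raise ValueError("channel names must be unique")

    @property
    def all_channels(self) -> tuple[str, ...]:
        return self.nk_markers + self.dump_markers + (self.viability_marker,)


DEFAULT_PANEL = MarkerPanel()


@dataclass
class EventMatrix:
    """Per-sample fluorescence table: one row per event, one column per channel.

    ``transform`` tags the scale the values live on so downstream stages
    cannot silently mix raw and transformed intensities.
    """

    data: pd.DataFrame
    sample_id: str = ""
    transform: str = "raw"
    transform_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("channel names must be unique")
        if len(self.data) and not np.isfinite(self.data.to_numpy(float)).all():
            raise ValueError("event values must be finite")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def values(self, channels: Sequence[str] | None = None) -> np.ndarray:
        cols = list(channels) if channels is not None else self.channels
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise MissingChannelError(missing)
        return self.data[cols].to_numpy(float)


@dataclass
class GateResult:
    """Audit record of a gate: which events were kept and with what cutoffs."""

    kept_indices: np.ndarray
    gate_name: str
    thresholds_used: dict[str, float]
    n_input: int

    @property
    def n_kept(self) -> int:
        return int(len(self.kept_indices))


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix == ".fcs":
        return "fcs"
    if suffix in (".csv", ".txt", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_events(
    path: str | Path,
    format: str = "auto",
    channel_map: Mapping[str, str] | None = None,
    required_channels: Sequence[str] | None = None,
    sample_id: str | None = None,
) -> EventMatrix:
    """Read an event table from FCS 3.x or headered delimited text.

    ``channel_map`` renames instrument channel names (e.g. detector labels)
    to panel marker names before the required-channel check.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "fcs":
        data = read_fcs(path)
    elif fmt == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        data = pd.read_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if channel_map:
        data = data.rename(columns=dict(channel_map))
    if required_channels is not None:
        missing = [c for c in required_channels if c not in data.columns]
        if missing:
            raise MissingChannelError(missing)
    return EventMatrix(
        data=data, sample_id=sample_id if sample_id is not None else path.stem
    )


def write_events(matrix: EventMatrix, path: str | Path, format: str = "auto") -> None:
    """Write an event table as FCS 3.1 or headered CSV."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "fcs":
        write_fcs(path, matrix.data)
    elif fmt == "csv":
        matrix.data.to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def transform_events(
    matrix: EventMatrix, method: str = "arcsinh", params: Mapping[str, float] | None = None
) -> EventMatrix:
    """Apply a monotone per-channel variance-stabilising transform.

    Methods: ``identity``; ``arcsinh`` with cofactor ``c`` (x -> asinh(x/c));
    ``log`` (x -> log10(1 + x/c), defined for x > -c). The transform tag of
    the returned matrix records the method and parameters.
    """
    params = dict(params or {})
    if method == "identity":
        new = matrix.data.copy()
    elif method in ("arcsinh", "log"):
        c = float(params.get("cofactor", 150.0))
        if c <= 0:
            raise ValueError("cofactor must be > 0 for a monotone transform")
        params["cofactor"] = c
        values = matrix.data.to_numpy(float)
        if method == "arcsinh":
            out = np.arcsinh(values / c)
        else:
            shifted = 1.0 + values / c
            if (shifted <= 0).any():
                raise ValueError("log transform undefined for values <= -cofactor")
            out = np.log10(shifted)
        new = pd.DataFrame(out, columns=matrix.data.columns, index=matrix.data.index)
    else:
        raise ValueError(f"unknown transform {method!r}")
    return EventMatrix(
        data=new,
        sample_id=matrix.sample_id,
        transform=method if matrix.transform in ("raw", "identity") else f"{matrix.transform}+{method}",
        transform_params=params,
    )


def gate_nk(
    matrix: EventMatrix,
    thresholds: Mapping[str, float],
    panel: MarkerPanel = DEFAULT_PANEL,
) -> GateResult:
    """Select viable, dump-negative NK events.

    An event is kept when every dump channel and the viability channel are at
    or below their cutoffs and the event is CD56+CD16+, CD56+CD16- or
    CD56-CD16+ (i.e. not double-negative for CD56/CD16).
    """
    required = list(panel.dump_markers) + [
        panel.viability_marker,
        panel.nk_markers[0],
        panel.nk_markers[1],
    ]
    missing_thr = [c for c in required if c not in thresholds]
    if missing_thr:
        raise ValueError(f"thresholds missing for channels: {missing_thr}")
    used = {c: float(thresholds[c]) for c in required}

    # a threshold is degenerate when it can empty the gate: a dump/viability
    # cutoff below the channel minimum excludes everything; a CD56/CD16
    # cutoff above the maximum yields no positive events on that channel
    positive_channels = (panel.nk_markers[0], panel.nk_markers[1])
    for chan, cut in used.items():
        if not matrix.n_events:
            continue
        col = matrix.values([chan])[:, 0]
        degenerate = (
            cut > col.max() if chan in positive_channels else cut < col.min()
        )
        if degenerate:
            logger.warning(
                "gate threshold %.3g for %s is outside the data range "
                "[%.3g, %.3g]; the gate may be empty",
                cut, chan, col.min(), col.max(),
            )

    if matrix.n_events == 0:
        kept = np.empty(0, dtype=int)
    else:
        clean = np.ones(matrix.n_events, dtype=bool)
        for chan in list(panel.dump_markers) + [panel.viability_marker]:
            clean &= matrix.values([chan])[:, 0] <= used[chan]
        cd56 = matrix.values([panel.nk_markers[0]])[:, 0] > used[panel.nk_markers[0]]
        cd16 = matrix.values([panel.nk_markers[1]])[:, 0] > used[panel.nk_markers[1]]
        kept = np.flatnonzero(clean & (cd56 | cd16))
    return GateResult(
        kept_indices=kept, gate_name="NK", thresholds_used=used, n_input=matrix.n_events
    )


def apply_gate(matrix: EventMatrix, gate: GateResult) -> EventMatrix:
    """Return the gated subset as a new EventMatrix (indices reset)."""
    sub = matrix.data.iloc[gate.kept_indices].reset_index(drop=True)
    return EventMatrix(
        data=sub,
        sample_id=matrix.sample_id,
        transform=matrix.transform,
        transform_params=dict(matrix.transform_params),
    )


def write_gate_log(gate: GateResult, path: str | Path) -> None:
    """Append-style tab-delimited audit line for a gate."""
    path = Path(path)
    header = "gate_name\tn_input\tn_kept\tthresholds\n"
    thr = ";".join(f"{k}={v:.6g}" for k, v in sorted(gate.thresholds_used.items()))
    line = f"{gate.gate_name}\t{gate.n_input}\t{gate.n_kept}\t{thr}\n"
    if not path.exists():
        path.write_text(header + line)
    else:
        with path.open("a") as fh:
            fh.write(line)


def _kde_valley(values: np.ndarray, grid_size: int = 512) -> float | None:
    """Cutoff at the density minimum between the two lowest-lying modes.

    Returns None when the kernel density estimate has fewer than two modes
    (unimodal or degenerate channel).
    """
    if np.ptp(values) == 0:
        return None
    sub = values if len(values) <= 5000 else values[:: len(values) // 5000]
    try:
        kde = gaussian_kde(sub)
    except np.linalg.LinAlgError:
        return None
    grid = np.linspace(values.min(), values.max(), grid_size)
    dens = kde(grid)
    floor = 0.05 * dens.max()
    peaks = [
        i
        for i in range(1, grid_size - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1] and dens[i] > floor
    ]
    if len(peaks) < 2:
        return None
    lo, hi = peaks[0], peaks[1]
    return float(grid[lo + int(np.argmin(dens[lo : hi + 1]))])


def auto_thresholds(
    matrix: EventMatrix,
    channels: Sequence[str],
    rule: str = "midpoint-between-modes",
    quantile: float = 0.99,
) -> dict[str, float]:
    """Derive deterministic per-channel cutoffs.

    ``midpoint-between-modes`` places the cutoff at the KDE valley between
    the two lowest-intensity modes; channels without two modes fall back to
    the ``fixed-quantile`` rule (logged). ``fixed-quantile`` uses the given
    quantile directly.
    """
    if rule not in ("midpoint-between-modes", "fixed-quantile"):
        raise ValueError(f"unknown threshold rule {rule!r}")
    cuts: dict[str, float] = {}
    for chan in channels:
        col = matrix.values([chan])[:, 0]
        cut = None
        if rule == "midpoint-between-modes":
            cut = _kde_valley(col)
            if cut is None:
                logger.warning(
                    "channel %s not bimodal; falling back to %.2f-quantile cutoff",
                    chan, quantile,
                )
        if cut is None:
            cut = float(np.quantile(col, quantile))
        cuts[chan] = cut
    return cuts


__all__ = [
    "MarkerPanel",
    "EventMatrix",
    "GateResult",
    "MissingChannelError",
    "FCSError",
    "DEFAULT_PANEL",
    "NK_MARKERS",
    "DUMP_MARKERS",
    "VIABILITY_MARKER",
    "read_events",
    "write_events",
    "transform_events",
    "gate_nk",
    "apply_gate",
    "write_gate_log",
    "auto_thresholds",
]
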