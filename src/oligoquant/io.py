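"""Plain-text and TIFF I/O for all toolbox data types.

Decay histograms, IRF/AF profiles, bleaching traces, correlation curves and
apoptosis event lists travel as delimited text with ``#`` comment headers;
channel/period/bin metadata lives in JSON sidecars or manifests; images are
16-bit grayscale TIFF.  Vendor TCSPC containers are deliberately not
parsed — exporting to these text formats is the contract.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .decay_models import DecayHistogram
from .dynamics import ApoptosisSeries
from .fcs import CorrelationCurve
from .pbsa import BleachTrace

__all__ = [
    "read_decay",
    "write_decay",
    "read_profile_column",
    "read_trace",
    "write_trace",
    "read_curve",
    "write_curve",
    "read_events",
    "write_events",
    "read_image",
    "write_image",
    "read_manifest",
]


def read_decay(path: str | Path, period: float, channel: str = "VM") -> DecayHistogram:
    """Read a (time_ns, counts) decay table."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_ns, counts)")
    return DecayHistogram(
        counts=data[:, 1], bin_times=data[:, 0], period=period, channel=channel
    )


def write_decay(path: str | Path, hist: DecayHistogram) -> None:
    header = f"channel={hist.channel} period_ns={hist.period}\ntime_ns\tcounts"
    np.savetxt(
        path,
        np.column_stack([hist.bin_times, hist.counts]),
        fmt=["%.9f", "%.0f"],
        delimiter="\t",
        header=header,
    )


def read_profile_column(path: str | Path) -> np.ndarray:
    """Read the amplitude column of an IRF/AF profile table."""
    data = np.loadtxt(path, comments="#")
    return data[:, 1] if data.ndim == 2 else data


def read_trace(path: str | Path, t_bin_s: float = 5e-3, power_uw: float = 1.36) -> BleachTrace:
    """Read a (bin_index, counts) bleaching-trace table."""
    data = np.loadtxt(path, comments="#")
    counts = data[:, 1] if data.ndim == 2 else data
    return BleachTrace(counts=counts, t_bin_s=t_bin_s, power_uw=power_uw)


def write_trace(path: str | Path, trace: BleachTrace) -> None:
    header = f"t_bin_s={trace.t_bin_s} power_uw={trace.power_uw}\nbin\tcounts"
    np.savetxt(
        path,
        np.column_stack([np.arange(trace.n_bins), trace.counts]),
        fmt=["%d", "%.0f"],
        delimiter="\t",
        header=header,
    )


def read_curve(path: str | Path) -> CorrelationCurve:
    """Read a (lag_s, G, stderr) correlation-curve table."""
    data = np.loadtxt(path, comments="#")
    stderr = data[:, 2] if data.shape[1] > 2 else None
    return CorrelationCurve(lag_s=data[:, 0], g=data[:, 1], stderr=stderr)


def write_curve(path: str | Path, curve: CorrelationCurve) -> None:
    cols = [curve.lag_s, curve.g]
    header = "lag_s\tG"
    if curve.stderr is not None:
        cols.append(curve.stderr)
        header += "\tstderr"
    np.savetxt(path, np.column_stack(cols), delimiter="\t", header=header)


def read_events(path: str | Path, n_cells: int | None = None) -> ApoptosisSeries:
    """Read a (cell_id, death_time_h) event list; NaN times mean censored."""
    df = pd.read_csv(path, sep="\t", comment="#")
    times = df["death_time_h"].to_numpy(dtype=float)
    total = n_cells if n_cells is not None else len(df)
    return ApoptosisSeries(event_times_h=times[np.isfinite(times)], n_cells=total)


def write_events(path: str | Path, series: ApoptosisSeries) -> None:
    rows = [
        {"cell_id": f"cell{i}", "death_time_h": t}
        for i, t in enumerate(series.event_times_h)
    ]
    for i in range(series.event_times_h.size, series.n_cells):
        rows.append({"cell_id": f"cell{i}", "death_time_h": np.nan})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
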