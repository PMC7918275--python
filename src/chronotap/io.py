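"""CSV readers/writers and the results manifest.

Default event CSV dialect: columns ``t`` (epoch seconds or ISO-8601) and
``kind``; wearable CSV: ``t`` plus either ``counts`` or ``ax,ay,az`` (or a
precomputed ``accel``) and ``lux``. Column names are remappable through a
column map so foreign exports can be ingested without rewriting files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import EVENT_KINDS, EventStream, WearableSeries

__all__ = [
    "read_event_stream",
    "write_event_stream",
    "read_wearable",
    "write_wearable",
    "write_results",
]


class FormatError(ValueError):
    """Raised for unparseable or grammar-violating input files."""


def _parse_times(col: pd.Series, path: Path) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    try:
        ts = pd.to_datetime(col, utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp column: {exc}") from exc
    return ts.astype("int64").to_numpy() / 1e9


def read_event_stream(
    path: str | Path,
    subject_id: str | None = None,
    column_map: dict[str, str] | None = None,
    strict: bool = True,
    utc_offset_s: float = 0.0,
) -> EventStream:
    """Load a touchscreen event CSV into a sorted, validated EventStream.

    Parameters
    ----------
    column_map
        Maps logical names {"t", "kind"} to the file's column names.
    strict
        If True, an unknown event kind is a :class:`FormatError` naming the
        offending row; if False, unknown kinds are dropped.
    """
    path = Path(path)
    cols = {"t": "t", "kind": "kind"}
    cols.update(column_map or {})
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty event file")
    missing = [v for v in (cols["t"], cols["kind"]) if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t = _parse_times(df[cols["t"]], path)
    kind = df[cols["kind"]].astype(str).to_numpy(dtype=object)
    unknown = ~np.isin(kind, EVENT_KINDS)
    if unknown.any():
        if strict:
            row = int(np.flatnonzero(unknown)[0])
            raise FormatError(
                f"{path}: unknown event kind {kind[row]!r} at row {row}"
            )
        t, kind = t[~unknown], kind[~unknown]
    order = np.argsort(t, kind="stable")
    return EventStream(
        subject_id=subject_id or path.stem,
        t=t[order],
        kind=kind[order],
        utc_offset_s=utc_offset_s,
    )


def write_event_stream(stream: EventStream, path: str | Path) -> None:
    pd.DataFrame({"t": stream.t, "kind": stream.kind}).to_csv(path, index=False)


def read_wearable(
    path: str | Path,
    epoch_s: float = 60.0,
    subject_id: str | None = None,
    column_map: dict[str, str] | None = None,
    utc_offset_s: float = 0.0,
) -> WearableSeries:
    """Load a wearable CSV, regularized to ``epoch_s`` epochs.

    Raw samples are aggregated per epoch (mean accel magnitude / summed
    counts / mean lux); epochs with no samples are marked missing (NaN).
    Duplicate timestamps are an error.
    """
    path = Path(path)
    cols = {"t": "t", "counts": "counts", "accel": "accel",
            "ax": "ax", "ay": "ay", "az": "az", "lux": "lux"}
    cols.update(column_map or {})
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty wearable file")
    t = _parse_times(df[cols["t"]], path)
    dup = pd.Series(t).duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicate timestamp {t[dup.idxmax()]:.3f}")

    if cols["counts"] in df.columns:
        signal = df[cols["counts"]].to_numpy(dtype=float)
        mode = "counts"
    elif cols["accel"] in df.columns:
        signal = df[cols["accel"]].to_numpy(dtype=float)
        mode = "accel"
    elif all(df.columns.__contains__(cols[a]) for a in ("ax", "ay", "az")):
        signal = np.sqrt(
            df[cols["ax"]].to_numpy(float) ** 2
            + df[cols["ay"]].to_numpy(float) ** 2
            + df[cols["az"]].to_numpy(float) ** 2
        )
        mode = "accel"
    else:
        raise FormatError(f"{path}: need a counts, accel, or ax/ay/az column")
    if cols["lux"] not in df.columns:
        raise FormatError(f"{path}: missing lux column")
    lux = df[cols["lux"]].to_numpy(dtype=float)

    t0 = np.floor(t.min() / epoch_s) * epoch_s
    idx = np.floor((t - t0) / epoch_s).astype(np.int64)
    n = int(idx.max()) + 1
    nsamp = np.bincount(idx, minlength=n).astype(float)
    with np.errstate(invalid="ignore"):
        if mode == "counts":
            sig_epoch = np.bincount(idx, weights=signal, minlength=n)
        else:
            sig_epoch = np.bincount(idx, weights=signal, minlength=n) / nsamp
        lux_epoch = np.bincount(idx, weights=lux, minlength=n) / nsamp
    empty = nsamp == 0
    sig_epoch = np.where(empty, np.nan, sig_epoch)
    lux_epoch = np.where(empty, np.nan, lux_epoch)

    kwargs = {"counts": sig_epoch} if mode == "counts" else {"accel_mag": sig_epoch}
    return WearableSeries(
        subject_id=subject_id or path.stem,
        t_start=t0 + epoch_s * np.arange(n),
        epoch_s=epoch_s,
        lux=lux_epoch,
        utc_offset_s=utc_offset_s,
        **kwargs,
    )


def write_wearable(series: WearableSeries, path: str | Path) -> None:
    cols = {"t": series.t_start}
    if series.counts is not None:
        cols["counts"] = series.counts
    if series.accel_mag is not None:
        cols["accel"] = series.accel_mag
    cols["lux"] = series.lux
    pd.DataFrame(cols).to_csv(path, index=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Write result tables as CSV plus a JSON manifest embedding the run config.

    The manifest is deterministic for a fixed config/seed/tables (keys sorted,
    no timestamps), so re-runs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": (config or AnalysisConfig()).to_dict(),
        "seed": seed,
        "tables": {},
    }
    for name in sorted(tables):
        df = tables[name]
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False)
        manifest["tables"][name] = {
            "file": fname,
            "rows": int(len(df)),
            "columns": list(df.columns),
        }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
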