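"""Delimited-table readers and writers.

All space-time fields travel as long-form CSV tables with an (s, t) key
pair per row; round-trips are lossless to better than 1e-12 (17 significant
digits are written).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError

_FLOAT_FMT = "%.17g"

MIDLINE_COLUMNS = ("s", "t", "x", "y", "theta", "kappa", "kappadot",
                   "vx", "vy", "ax", "ay")


def field_to_frame(s: np.ndarray, t: np.ndarray, **fields: np.ndarray) -> pd.DataFrame:
    """Long-form DataFrame of (Ns, Nt) fields keyed by (s, t)."""
    ns, nt = len(s), len(t)
    data = {"s": np.repeat(s, nt), "t": np.tile(t, ns)}
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape != (ns, nt):
            raise FormatError(f"field {name!r} has shape {arr.shape}, "
                              f"expected {(ns, nt)}")
        data[name] = arr.reshape(-1)
    return pd.DataFrame(data)


def write_field(path, s, t, **fields) -> None:
    field_to_frame(s, t, **fields).to_csv(path, index=False, float_format=_FLOAT_FMT)


def frame_to_field(
    df: pd.DataFrame, columns: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Validate a long-form table and pivot it back to (Ns, Nt) arrays.

    Raises FormatError on missing columns, NaNs, or a ragged (s, t) grid,
    naming the offending row where possible.
    """
    missing = [c for c in ("s", "t", *columns) if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    sub = df[["s", "t", *columns]]
    bad = sub.isna().any(axis=1)
    if bad.any():
        raise FormatError(f"NaN in row {int(np.flatnonzero(bad.to_numpy())[0])}")
    s = np.unique(sub["s"].to_numpy())
    t = np.unique(sub["t"].to_numpy())
    if len(sub) != len(s) * len(t):
        raise FormatError(
            f"table has {len(sub)} rows but the (s, t) grid implies "
            f"{len(s)}x{len(t)} = {len(s) * len(t)}; grid is ragged or has "
            "duplicate cells"
        )
    ordered = sub.sort_values(["s", "t"], kind="mergesort")
    # verify every (s, t) cell is present exactly once
    s_rep = np.repeat(s, len(t))
    t_rep = np.tile(t, len(s))
    if (np.max(np.abs(ordered["s"].to_numpy() - s_rep)) > 0
            or np.max(np.abs(ordered["t"].to_numpy() - t_rep)) > 0):
        first = int(np.flatnonzero(
            (ordered["s"].to_numpy() != s_rep) | (ordered["t"].to_numpy() != t_rep)
        )[0])
        raise FormatError(f"ragged (s, t) grid near sorted row {first}")
    out = {c: ordered[c].to_numpy().reshape(len(s), len(t)) for c in columns}
    return s, t, out


def read_field(path, columns: tuple[str, ...]):
    return frame_to_field(
        pd.read_csv(path, float_precision="round_trip"), columns)


def write_midline(path, midline) -> None:
    write_field(
        path, midline.s, midline.t,
        x=midline.x, y=midline.y, theta=midline.theta,
        kappa=midline.kappa, kappadot=midline.kappadot,
        vx=midline.vx, vy=midline.vy, ax=midline.ax, ay=midline.ay,
    )


def read_midline(path):
    from .kinematics import MidlineState

    s, t, f = read_field(path, MIDLINE_COLUMNS[2:])
    return MidlineState(s=s, t=t, frame="momentum-conserving", **f)


def write_body(path, body) -> None:
    pd.DataFrame({
        "s": body.s, "m_b": body.m_b, "h": body.h, "w": body.w,
        "m_a": body.m_a, "c_n": body.c_n, "c_t": body.c_t,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_body(path):
    from .bodies import BodyModel

    df = pd.read_csv(path, float_precision="round_trip")
    cols = ("s", "m_b", "h", "w", "m_a", "c_n", "c_t")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    return BodyModel(**{c: df[c].to_numpy() for c in cols})
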