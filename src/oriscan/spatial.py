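"""Spatial mapping of substitution events: site tables, windows, outliers.

The unit of analysis is the protein-coding alignment site.  Each analyzed
site gets a row carrying its ancestral genomic position, its origin-relative
distance (via the bidirectional transform), the number of substitution
events inferred at it (multiple hits on different branches all count), and
the binary indicator "at least one substitution" that feeds the logistic
regression.  Window summaries divide total substitutions by the number of
coding sites per distance window (default 10 kb) — the "substitutions per
10 kb" densities — with Tukey-fence outlier flagging.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .ancestral import SubstitutionEvent
from .blocks import GeneSegment
from .replicon import Replicon, Topology, transform_distances

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000
#: the window widths used for the supplementary windowed regressions, in bp
WINDOW_WIDTHS = (10_000, 25_000, 50_000, 100_000, 200_000, 400_000)

SITE_COLUMNS = [
    "segment",
    "column",
    "position",
    "distance",
    "signed",
    "count",
    "indicator",
    "replicon",
]


def build_site_table(
    events: Sequence[SubstitutionEvent],
    segments: Sequence[GeneSegment],
    replicon: Replicon,
    site_positions: Dict[str, np.ndarray],
) -> pd.DataFrame:
    """One row per analyzed coding site, with event counts and distances.

    ``site_positions`` maps segment id → per-column ancestral genomic
    position for sites with no events (the root reconstruction); sites with
    events take the parent-node position of their (first) event, so the
    three-taxon worked example lands at the ancestral position of the
    changed site.
    """
    frames: List[pd.DataFrame] = []
    for seg in segments:
        pos = np.asarray(site_positions[seg.id], dtype=np.int64)
        if pos.shape[0] != seg.length:
            raise ValueError(f"segment {seg.id}: position vector length mismatch")
        frames.append(
            pd.DataFrame(
                {
                    "segment": seg.id,
                    "column": np.arange(seg.length),
                    "position": pos,
                    "count": 0,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    table = pd.concat(frames, ignore_index=True)

    if events:
        ev = pd.DataFrame(
            {
                "segment": [e.segment_id for e in events],
                "column": [e.column for e in events],
                "parent_position": [e.parent_position for e in events],
            }
        )
        agg = (
            ev.groupby(["segment", "column"], sort=False)
            .agg(ev_count=("parent_position", "size"), ev_position=("parent_position", "first"))
            .reset_index()
        )
        table = table.merge(agg, on=["segment", "column"], how="left", validate="1:1")
        hit = table["ev_count"].notna()
        if int(hit.sum()) != agg.shape[0]:
            raise KeyError("substitution events at sites absent from the segment set")
        table.loc[hit, "count"] = table.loc[hit, "ev_count"].astype(int)
        table.loc[hit, "position"] = table.loc[hit, "ev_position"].astype(np.int64)
        table = table.drop(columns=["ev_count", "ev_position"])
    bad = (table["position"] < 1) | (table["position"] > replicon.length)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} site positions outside replicon {replicon.name}"
        )
    distance, signed = transform_distances(table["position"].to_numpy(), replicon)
    table["distance"] = distance
    table["signed"] = signed if signed is not None else np.nan
    table["indicator"] = (table["count"] >= 1).astype(int)
    table["replicon"] = replicon.name
    return table[SITE_COLUMNS]


def window_aggregate(table: pd.DataFrame, w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Half-open windows [k·w, (k+1)·w) over transformed distance.

    ``density`` is substitutions per coding site within the window (the
    per-10-kb density when ``w`` is 10 kb).  Windows with no coding sites
    get a NaN density and are excluded from regressions.
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    out_cols = ["window", "start", "end", "n_sites", "n_events", "density", "outlier"]
    if table.empty:
        return pd.DataFrame(columns=out_cols)
    idx = (table["distance"] // w).astype(int)
    grouped = table.groupby(idx).agg(
        n_sites=("indicator", "size"), n_events=("count", "sum")
    )
    n_windows = int(table["distance"].max() // w) + 1
    grouped = grouped.reindex(range(n_windows), fill_value=0)
    win = grouped.reset_index(names="window")
    win["start"] = win["window"] * w
    win["end"] = win["start"] + w
    win["density"] = np.where(
        win["n_sites"] > 0, win["n_events"] / win["n_sites"].replace(0, 1), np.nan
    )
    win["outlier"] = flag_outliers(win["density"].to_numpy())
    return win[out_cols]


def flag_outliers(values: Iterable[float], mode: str = "tukey") -> np.ndarray:
    """Boolean mask of outlying values.

    ``tukey`` (default): outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by
    linear interpolation.  ``literal``: outside [Q1, Q3] — the strict
    reading of "outside the interquartile range", kept behind this switch
    because it discards half the data.  NaNs are never flagged.
    """
    v = np.asarray(list(values), dtype=float)
    mask = np.zeros(v.shape[0], dtype=bool)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        if v.size:
            logger.warning("fewer than 4 finite values; no outliers flagged")
        return mask
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    if mode == "tukey":
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    elif mode == "literal":
        lo, hi = q1, q3
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    mask[finite] = (v[finite] < lo) | (v[finite] > hi)
    return mask


def mean_substitutions_per_bp(
    table: pd.DataFrame, outlier_windows: Optional[pd.DataFrame] = None, w: int = DEFAULT_WINDOW
) -> float:
    """Average substitutions per analyzed coding bp, outlier windows excluded."""
    if table.empty:
        return float("nan")
    if outlier_windows is None:
        outlier_windows = window_aggregate(table, w)
    bad = set(outlier_windows.loc[outlier_windows["outlier"], "window"])
    keep = ~(table["distance"] // w).astype(int).isin(bad)
    kept = table[keep]
    if kept.empty:
        return float("nan")
    return float(kept["count"].sum() / len(kept))


def site_table_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def windows_to_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False)
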