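"""Rao quadratic entropy on trait-space distances, and diversity trends.

Rao's quadratic entropy combines relative abundances ``p`` with pairwise
functional distances ``d``:

    Q = Σ_i Σ_j p_i p_j d_ij

(full double sum; each unordered pair counted twice; no division by
Simpson's index).  ``half=True`` exposes the ×1/2 convention.  ``Q`` is in
the units of the distance matrix, is zero for a single-species sample and
bounded above by the largest pairwise distance.

Species missing from the trait space are dropped and the composition
renormalised; the retained biomass fraction is reported as *coverage* so
unreliable estimates can be flagged instead of silently biased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance_io import AbundanceTable
from .diffusion_map import DistanceMatrix, TraitSpace, diffusion_distance

logger = logging.getLogger(__name__)

__all__ = ["DiversityRecord", "rao_index", "sample_diversity_series",
           "diversity_frame", "station_trend"]


@dataclass
class DiversityRecord:
    """Per-sample functional diversity estimate."""

    sample_id: str
    Q: float  # NaN when undefined (zero covered biomass)
    n_effective_species: int
    coverage: float
    flagged: bool = False


def rao_index(p: np.ndarray, D: DistanceMatrix | np.ndarray, *,
              half: bool = False) -> float:
    """Quadratic entropy ``Σ_ij p_i p_j d_ij`` of composition ``p``."""
    d = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.shape[0] != d.shape[0]:
        raise ValueError(f"composition length {p.shape[0]} does not match "
                         f"distance matrix size {d.shape[0]}")
    q = float(p @ d @ p)
    return 0.5 * q if half else q


def sample_diversity_series(t: AbundanceTable, ts: TraitSpace, *,
                            coverage_floor: float = 0.5,
                            half: bool = False) -> list[DiversityRecord]:
    """Rao diversity of every sample, using diffusion distances from ``ts``.

    For each sample, species absent from the trait space are dropped, the
    composition is renormalised, and the coverage (retained biomass
    fraction) recorded.  Samples below ``coverage_floor`` — or with no
    covered biomass at all, in which case ``Q`` is NaN — are flagged.
    """
    pos = {s: i for i, s in enumerate(ts.species_ids)}
    shared = [i for i, s in enumerate(t.species_ids) if s in pos]
    if not shared:
        raise ValueError("no species shared between table and trait space")
    ids = [t.species_ids[i] for i in shared]
    D = diffusion_distance(ts, ids).D
    sub = t.biomass[shared]
    records = []
    for j, sid in enumerate(t.sample_ids):
        col = t.biomass[:, j]
        total = col.sum()
        covered = sub[:, j].sum()
        coverage = float(covered / total) if total > 0 else 0.0
        if covered <= 0:
            records.append(DiversityRecord(sid, float("nan"), 0, coverage, True))
            continue
        p = sub[:, j] / covered
        q = float(p @ D @ p)
        records.append(DiversityRecord(
            sid, 0.5 * q if half else q, int((p > 0).sum()), coverage,
            coverage < coverage_floor))
    n_flagged = sum(r.flagged for r in records)
    if n_flagged:
        logger.warning("%d of %d samples flagged (coverage < %.2f or undefined)",
                       n_flagged, len(records), coverage_floor)
    return records


def diversity_frame(records: list[DiversityRecord],
                    t: AbundanceTable | None = None) -> pd.DataFrame:
    """Tabulate records, joining station/date metadata when available."""
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("sample_id")
    if t is not None and t.sample_meta is not None:
        keep = [c for c in ("station", "date") if c in t.sample_meta.columns]
        df = df.join(t.sample_meta[keep])
    return df.reset_index()


def _decimal_year(dates: pd.Series) -> np.ndarray:
    d = pd.to_datetime(dates)
    start = pd.to_datetime(d.dt.year.astype(str))
    end = pd.to_datetime((d.dt.year + 1).astype(str))
    return (d.dt.year + (d - start).dt.total_seconds()
            / (end - start).dt.total_seconds()).to_numpy()


def station_trend(df: pd.DataFrame) -> pd.DataFrame:
    """Per-station OLS trend of Rao diversity on decimal year.

    Expects columns ``station``, ``date`` and ``Q``; undated or flagged
    rows are excluded with a warning.  Returns one row per station with
    ``slope`` (Q units per year), ``intercept``, two-sided ``p``,
    ``mean_Q`` and ``n``, sorted by slope descending.
    """
    df = df.copy()
    bad = df["date"].isna() | df["Q"].isna()
    if "flagged" in df.columns:
        bad |= df["flagged"].astype(bool)
    if bad.any():
        logger.warning("station_trend: excluding %d undated/flagged records",
                       int(bad.sum()))
        df = df[~bad]
    rows = []
    for station, g in df.groupby("station"):
        if len(g) < 3:
            logger.warning("station %r has < 3 dated records; skipped", station)
            continue
        year = _decimal_year(g["date"])
        res = stats.linregress(year, g["Q"].to_numpy())
        rows.append({"station": station, "slope": res.slope,
                     "intercept": res.intercept, "p": res.pvalue,
                     "mean_Q": g["Q"].mean(), "n": len(g)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("slope", ascending=False, ignore_index=True)
    return out
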