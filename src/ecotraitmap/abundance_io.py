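"""Reading, validation and reshaping of species-by-sample abundance tables.

The only required input of the trait-inference pipeline is a nonnegative
species × sample matrix of biomasses (or abundances; units are arbitrary but
must be consistent within a table), optionally accompanied by per-sample
metadata (station, date, environmental covariates).

Conventions
-----------
* A species not recorded in a sample is *absent*: its biomass is 0.  NaN
  cells on ingestion are mapped to 0 (monitoring datasets record presences);
  the number of such cells is logged.
* Samples whose total biomass is 0 after ingestion are dropped with a
  warning — a sample with nothing in it carries no compositional
  information.
* Wide-layout orientation (species rows vs. sample rows) is an explicit
  flag, never guessed: silent transposition is a classic data-corruption
  bug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "filter_species",
    "relative_composition",
]

#: columns of a long-layout file that are not covariates
_LONG_CORE = ("species_id", "sample_id", "value")


class AbundanceValidationError(ValueError):
    """Raised when a table violates the abundance-matrix invariants."""


@dataclass
class AbundanceTable:
    """Nonnegative species × sample biomass matrix with sample metadata.

    Parameters
    ----------
    species_ids
        Ordered unique species identifiers (rows of ``biomass``).
    sample_ids
        Ordered unique sample identifiers (columns of ``biomass``).
    biomass
        Array of shape ``(n_species, n_samples)``; nonnegative, no NaN.
    sample_meta
        Optional per-sample records indexed by sample id.  Recognised
        columns are ``station`` (str), ``date`` (ISO-8601, parsed to
        datetime) and arbitrary numeric covariates.
    """

    species_ids: list[str]
    sample_ids: list[str]
    biomass: np.ndarray
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.species_ids = [str(s) for s in self.species_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.biomass.shape != (len(self.species_ids), len(self.sample_ids)):
            raise AbundanceValidationError(
                f"biomass shape {self.biomass.shape} does not match "
                f"{len(self.species_ids)} species × {len(self.sample_ids)} samples"
            )
        if len(set(self.species_ids)) != len(self.species_ids):
            raise AbundanceValidationError("duplicate species ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AbundanceValidationError("duplicate sample ids")
        n_nan = int(np.isnan(self.biomass).sum())
        if n_nan:
            logger.info("mapping %d NaN biomass cells to 0 (absence convention)", n_nan)
            self.biomass = np.nan_to_num(self.biomass, nan=0.0)
        if (self.biomass < 0).any():
            i, j = np.argwhere(self.biomass < 0)[0]
            raise AbundanceValidationError(
                f"negative biomass at species {self.species_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.biomass[i, j]}"
            )
        empty = self.biomass.sum(axis=0) == 0
        if empty.any():
            dropped = [s for s, e in zip(self.sample_ids, empty) if e]
            logger.warning("dropping %d empty samples: %s", len(dropped), dropped[:10])
            keep = ~empty
            self.biomass = self.biomass[:, keep]
            self.sample_ids = [s for s, k in zip(self.sample_ids, keep) if k]
            if self.sample_meta is not None:
                self.sample_meta = self.sample_meta.loc[
                    [s for s in self.sample_meta.index if s in set(self.sample_ids)]
                ]
        if self.sample_meta is not None:
            self.sample_meta = self.sample_meta.reindex(self.sample_ids)

    # -- container conveniences -------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"unknown species {species_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: species rows × sample columns."""
        return pd.DataFrame(self.biomass, index=self.species_ids, columns=self.sample_ids)

    def covariate(self, name: str) -> pd.Series:
        """Per-sample covariate values (may contain NaN for missing)."""
        if self.sample_meta is None or name not in self.sample_meta.columns:
            raise KeyError(f"unknown covariate {name!r}")
        return self.sample_meta[name]


def _parse_meta(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    if "date" in meta.columns:
        meta["date"] = pd.to_datetime(meta["date"], format="ISO8601")
    return meta


def _check_numeric(values: pd.DataFrame | pd.Series, what: str) -> np.ndarray:
    arr = pd.to_numeric(values.stack() if isinstance(values, pd.DataFrame) else values,
                        errors="coerce")
    raw = values.stack() if isinstance(values, pd.DataFrame) else values
    bad = arr.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        loc = bad.idxmax()
        raise AbundanceValidationError(f"malformed numeric cell in {what} at {loc!r}: "
                                       f"{raw.loc[loc]!r}")
    return arr


def read_abundance_table(
    path: str | Path,
    layout: str = "wide",
    *,
    orientation: str = "species_rows",
    sep: str = ",",
    meta_path: str | Path | None = None,
) -> AbundanceTable:
    """Read a delimited abundance table.

    ``layout="wide"``: a matrix with an id column/header row.  With
    ``orientation="species_rows"`` rows are species and columns samples;
    ``"sample_rows"`` reads the transpose.  ``layout="long"``: one
    ``(species_id, sample_id, value)`` record per row; any further columns
    are treated as per-sample metadata and must be constant within a
    sample.  Duplicate (species, sample) records are an error, never
    silently summed.

    Sample metadata may alternatively be supplied in a separate file keyed
    by ``sample_id`` via ``meta_path``.
    """
    path = Path(path)
    if layout == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        values = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
        bad = values.isna() & df.notna()
        if bad.any().any():
            j = bad.any().idxmax()
            i = bad[j].idxmax()
            raise AbundanceValidationError(
                f"malformed numeric cell at row {i!r}, column {j!r}: {df.loc[i, j]!r}")
        if orientation == "sample_rows":
            values = values.T
        elif orientation != "species_rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        species_ids = [str(s) for s in values.index]
        sample_ids = [str(s) for s in values.columns]
        biomass = values.to_numpy(dtype=float)
    elif layout == "long":
        df = pd.read_csv(path, sep=sep, dtype={c: str for c in _LONG_CORE[:2]})
        missing = [c for c in _LONG_CORE if c not in df.columns]
        if missing:
            raise AbundanceValidationError(f"long layout requires columns {missing}")
        dup = df.duplicated(subset=["species_id", "sample_id"])
        if dup.any():
            r = df[dup].iloc[0]
            raise AbundanceValidationError(
                f"duplicate record for species {r['species_id']!r}, "
                f"sample {r['sample_id']!r}")
        value = _check_numeric(df["value"], "column 'value'")
        pivot = df.assign(value=value).pivot(
            index="species_id", columns="sample_id", values="value")
        species_ids = [str(s) for s in pivot.index]
        sample_ids = [str(s) for s in pivot.columns]
        biomass = np.nan_to_num(pivot.to_numpy(dtype=float), nan=0.0)
        extra = [c for c in df.columns if c not in _LONG_CORE]
        if extra:
            meta = df[["sample_id", *extra]].drop_duplicates()
            if meta["sample_id"].duplicated().any():
                s = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
                raise AbundanceValidationError(
                    f"inconsistent metadata for sample {s!r}")
            meta = meta.set_index("sample_id").reindex(sample_ids)
            return AbundanceTable(species_ids, sample_ids, biomass, _parse_meta(meta))
    else:
        raise ValueError(f"unknown layout {layout!r}")

    sample_meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=sep, index_col="sample_id")
        meta.index = meta.index.astype(str)
        sample_meta = _parse_meta(meta)
    return AbundanceTable(species_ids, sample_ids, biomass, sample_meta)


def write_abundance_table(
    t: AbundanceTable,
    path: str | Path,
    layout: str = "wide",
    *,
    sep: str = ",",
) -> None:
    """Write a table back to delimited text (inverse of :func:`read_abundance_table`).

    Numeric cells round-trip bit-exactly (shortest-repr float formatting).
    Long layout writes only nonzero cells; zeros are implied by absence.
    """
    path = Path(path)
    if layout == "wide":
        t.to_frame().to_csv(path, sep=sep, index_label="species_id")
    elif layout == "long":
        rows = np.argwhere(t.biomass > 0)
        df = pd.DataFrame({
            "species_id": [t.species_ids[i] for i, _ in rows],
            "sample_id": [t.sample_ids[j] for _, j in rows],
            "value": [t.biomass[i, j] for i, j in rows],
        })
        df.to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def filter_species(t: AbundanceTable, min_occurrence: int = 5) -> AbundanceTable:
    """Retain species present (biomass > 0) in at least ``min_occurrence`` samples.

    Rank correlations over species observed in very few samples are
    dominated by ties, so sparse species are removed before similarity
    estimation.  The sample set is unchanged.  Idempotent for a fixed
    threshold.
    """
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be >= 1")
    occ = (t.biomass > 0).sum(axis=1)
    keep = occ >= min_occurrence
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_species: removed %d of %d species (min_occurrence=%d)",
                    n_removed, t.n_species, min_occurrence)
    if keep.sum() < 3:
        raise AbundanceValidationError(
            f"only {int(keep.sum())} species present in >= {min_occurrence} samples; "
            "trait inference needs at least 3")
    return AbundanceTable(
        [s for s, k in zip(t.species_ids, keep) if k],
        list(t.sample_ids),
        t.biomass[keep],
        None if t.sample_meta is None else t.sample_meta.copy(),
    )


def relative_composition(t: AbundanceTable, sample_id: str) -> np.ndarray:
    """Biomass shares ``p_i = B_i / Σ_j B_j`` of one sample (sums to 1)."""
    j = t.sample_index(sample_id)
    col = t.biomass[:, j]
    total = col.sum()
    if total <= 0:
        raise AbundanceValidationError(f"sample {sample_id!r} has zero total biomass")
    return col / total
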