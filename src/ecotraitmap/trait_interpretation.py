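"""Post-hoc interpretation of i-trait axes via environmental preferences.

Inferred trait axes are purely statistical constructs.  A biological
reading can be attached by computing, for every species, the
biomass-weighted mean of each environmental covariate over the samples in
which it occurs — its realised environmental preference — and correlating
these preferences with the species' coordinates on each i-trait axis
(Spearman).  The sign of an eigenvector is arbitrary, so |rS| is the
headline statistic; signed values are reported alongside.

Alignment of an axis with a covariate is a statistical association, not
evidence of a causal link: outputs are hypothesis-generating.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .abundance_io import AbundanceTable
from .diffusion_map import TraitSpace

logger = logging.getLogger(__name__)

__all__ = ["weighted_env_mean", "trait_env_correlation"]


def weighted_env_mean(t: AbundanceTable, covariate: str) -> pd.DataFrame:
    """Biomass-weighted mean covariate value per species.

    ``mean_i = Σ_s B_is e_s / Σ_s B_is`` over samples ``s`` where the
    covariate is recorded (missing covariates are excluded pairwise).
    Species never observed together with the covariate are omitted with a
    warning.  Returns columns ``species_id``, ``mean``, ``total_weight``.
    """
    e = pd.to_numeric(t.covariate(covariate), errors="raise").to_numpy(dtype=float)
    have = ~np.isnan(e)
    if not have.any():
        raise ValueError(f"covariate {covariate!r} has no recorded values")
    B = t.biomass[:, have]
    ev = e[have]
    weight = B.sum(axis=1)
    ok = weight > 0
    if (~ok).any():
        logger.warning("%d species have zero weight for covariate %r; omitted",
                       int((~ok).sum()), covariate)
    means = (B[ok] @ ev) / weight[ok]
    return pd.DataFrame({
        "species_id": [s for s, o in zip(t.species_ids, ok) if o],
        "mean": means,
        "total_weight": weight[ok],
    })


def trait_env_correlation(ts: TraitSpace, t: AbundanceTable,
                          covariates: list[str], n_axes: int | None = None
                          ) -> pd.DataFrame:
    """Spearman correlation of each i-trait axis with each covariate's
    per-species weighted environmental mean.

    Returns one row per (axis, covariate): ``rs`` (signed), ``abs_rs``,
    two-sided ``p`` and ``n_species``.  Requires at least 5 species shared
    between the trait space and the profiles.
    """
    n_axes = min(n_axes or ts.n_axes, ts.n_axes)
    pos = {s: i for i, s in enumerate(ts.species_ids)}
    rows = []
    for cov in covariates:
        prof = weighted_env_mean(t, cov)
        prof = prof[prof["species_id"].isin(pos)]
        if len(prof) < 5:
            raise ValueError(
                f"only {len(prof)} species shared with the trait space for "
                f"covariate {cov!r}; need at least 5")
        idx = [pos[s] for s in prof["species_id"]]
        means = prof["mean"].to_numpy()
        for axis in range(n_axes):
            res = spearmanr(ts.coords[idx, axis], means)
            rows.append({"axis": axis + 1, "covariate": cov,
                         "rs": float(res.statistic),
                         "abs_rs": abs(float(res.statistic)),
                         "p": float(res.pvalue), "n_species": len(idx)})
    return pd.DataFrame(rows)
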