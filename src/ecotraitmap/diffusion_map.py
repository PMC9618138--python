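"""Diffusion-map construction of an inferred trait ("i-trait") space.

The dissimilarity of two species is hard to quantify directly, but species
with very similar niches can be compared reliably through their
co-occurrence pattern: the Spearman rank correlation of their biomasses
across monitoring samples.  Keeping, for every species, only its ``k`` most
similar comparisons ("trusted links", union-kNN symmetrisation) yields a
sparse network that spans the species set while containing only
short-range — hence trustworthy — comparisons.

The graph Laplacian ``L = Diag(rowsum S) − S`` of the trusted network is
then eigendecomposed.  Each eigenvector ``v_n`` (nonzero eigenvalue
``λ_n``, ascending) defines one i-trait axis; the eigenvalue is inversely
proportional to the importance of the axis, so the properly scaled
coordinate of axis ``n`` is ``v_n / λ_n``.  Pairwise functional
dissimilarity is the diffusion distance

    d_ij² = Σ_n (v_{n,i} − v_{n,j})² / λ_n² ,

i.e. the Euclidean distance in the rescaled coordinates.  With all
downstream defaults in place the trusted-neighbour count ``k`` is the only
tunable parameter of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .abundance_io import AbundanceTable, filter_species

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "TrustedNetwork",
    "TraitSpace",
    "DistanceMatrix",
    "spearman_similarity",
    "trusted_links",
    "laplacian",
    "embed",
    "diffusion_distance",
    "infer_traits",
]


@dataclass
class SimilarityMatrix:
    """Dense symmetric matrix of pairwise Spearman similarities in [−1, 1]."""

    species_ids: list[str]
    S_full: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S_full, dtype=float)
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        off = S[~np.eye(len(S), dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-12).any():
            raise ValueError("similarities must lie in [-1, 1]")
        self.S_full = S


@dataclass
class TrustedNetwork:
    """Sparse symmetric network of trusted (top-k) similarity links.

    Stored weights are positive; the diagonal is zero.  By the union rule
    every node has degree at least ``min(k, n−1)`` unless its entire
    neighbourhood had negative similarity (such nodes become isolated and
    are reported).
    """

    species_ids: list[str]
    S: sparse.csr_matrix
    k: int

    def components(self) -> tuple[int, np.ndarray]:
        """Number of connected components and the component label per node."""
        return connected_components(self.S, directed=False)

    def giant_component_mask(self) -> np.ndarray:
        n_comp, labels = self.components()
        if n_comp > 1:
            logger.warning("trusted network has %d components", n_comp)
        return labels == np.bincount(labels).argmax()

    def degrees(self) -> np.ndarray:
        return np.asarray((self.S > 0).sum(axis=1)).ravel()


@dataclass
class TraitSpace:
    """Eigenvalue-rescaled Laplacian eigenvector coordinates of species.

    ``coords[:, n]`` is ``v_{n+2} / λ_{n+2}`` for the ``n``-th smallest
    *nonzero* eigenvalue (the constant zero-eigenvalue eigenvector is
    discarded).  Column norms are therefore non-increasing: later axes
    matter less.
    """

    species_ids: list[str]
    eigenvalues: np.ndarray
    coords: np.ndarray

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def to_csv(self, prefix: str | Path) -> None:
        """Write ``<prefix>eigenvalues.csv`` and ``<prefix>coords.csv``."""
        prefix = str(prefix)
        pd.DataFrame({"axis": np.arange(1, self.n_axes + 1),
                      "lambda": self.eigenvalues}).to_csv(
            prefix + "eigenvalues.csv", index=False)
        cols = {f"trait_{n + 1}": self.coords[:, n] for n in range(self.n_axes)}
        pd.DataFrame({"species_id": self.species_ids, **cols}).to_csv(
            prefix + "coords.csv", index=False)

    @classmethod
    def from_csv(cls, prefix: str | Path) -> "TraitSpace":
        prefix = str(prefix)
        ev = pd.read_csv(prefix + "eigenvalues.csv")
        co = pd.read_csv(prefix + "coords.csv")
        coords = co[[c for c in co.columns if c.startswith("trait_")]].to_numpy()
        return cls(co["species_id"].astype(str).tolist(),
                   ev["lambda"].to_numpy(), coords)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    species_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if not np.allclose(D, D.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (D < -1e-12).any() or not np.allclose(np.diag(D), 0, atol=1e-9):
            raise ValueError("distances must be nonnegative with zero diagonal")
        self.D = D

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.D, index=self.species_ids,
                     columns=self.species_ids).to_csv(path, index_label="species_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col="species_id")
        return cls([str(s) for s in df.index], df.to_numpy(dtype=float))

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in :func:`scipy.spatial.distance.pdist` order."""
        return squareform(self.D, checks=False)


# ---------------------------------------------------------------------------


def spearman_similarity(t: AbundanceTable) -> SimilarityMatrix:
    """Spearman rank correlation of biomass vectors between all species pairs.

    Zeros (absences) participate as tied ranks; ties receive average
    ranks.  A species whose biomass vector is constant across samples has
    an undefined rank correlation and triggers an error advising a higher
    occurrence filter.
    """
    if t.n_species < 3 or t.n_samples < 3:
        raise ValueError("need at least 3 species and 3 samples")
    B = t.biomass
    const = B.std(axis=1) == 0
    if const.any():
        bad = [s for s, c in zip(t.species_ids, const) if c]
        raise ValueError(
            f"species with constant biomass vector (undefined correlation): "
            f"{bad[:5]}; raise min_occurrence in filter_species")
    ranks = rankdata(B, axis=1)
    S = np.corrcoef(ranks)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(list(t.species_ids), S)


def trusted_links(sim: SimilarityMatrix, k: int = 10) -> TrustedNetwork:
    """Union-kNN sparsification: keep (i, j) iff j ranks in i's top ``k``
    similarities or vice versa.

    Ranking uses the signed similarity; ties at the k-th rank are all
    admitted (deterministic, order-independent).  Retained weights are
    clipped at zero — a negative correlation cannot act as a diffusion
    conductance — so a node whose whole top-k is negative becomes isolated
    (warned about, and excluded from the giant component downstream).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    S = sim.S_full.copy()
    n = len(S)
    np.fill_diagonal(S, -np.inf)
    keep = np.zeros((n, n), dtype=bool)
    kk = min(k, n - 1)
    for i in range(n):
        thresh = np.partition(S[i], n - kk)[n - kk]
        keep[i] = S[i] >= thresh
    keep |= keep.T
    W = np.where(keep, np.maximum(S, 0.0), 0.0)
    np.fill_diagonal(W, 0.0)
    W = np.maximum(W, W.T)
    isolated = int((W.sum(axis=1) == 0).sum())
    if isolated:
        logger.warning("%d nodes isolated after clipping negative weights", isolated)
    net = TrustedNetwork(list(sim.species_ids), sparse.csr_matrix(W), k)
    n_comp, _ = net.components()
    logger.info("trusted network: %d nodes, %d components", n, n_comp)
    return net


def laplacian(net: TrustedNetwork) -> tuple[np.ndarray, list[str]]:
    """Unnormalised graph Laplacian of the largest connected component.

    Returns ``(L, species_ids)`` where ``L = Diag(rowsum S) − S`` restricted
    to the giant component; species outside it are excluded (logged).
    """
    if net.S.nnz == 0:
        raise ValueError("empty trusted network")
    mask = net.giant_component_mask()
    n_out = int((~mask).sum())
    if n_out:
        logger.warning("laplacian: excluding %d species outside the giant component",
                       n_out)
    W = net.S.toarray()[np.ix_(mask, mask)]
    L = np.diag(W.sum(axis=1)) - W
    ids = [s for s, m in zip(net.species_ids, mask) if m]
    return L, ids


def _orient(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def embed(net: TrustedNetwork, n_axes: int = 20, *,
          normalization: str = "unnormalized") -> TraitSpace:
    """Spectral embedding: the ``n_axes`` smallest nonzero Laplacian eigenpairs.

    ``normalization="random_walk"`` solves the generalized problem
    ``L v = λ Diag(rowsum S) v`` instead (experimental alternative); the
    default is the unnormalised Laplacian.
    """
    L, ids = laplacian(net)
    n = len(ids)
    if n_axes < 1 or n_axes >= n:
        raise ValueError(f"need 1 <= n_axes < component size ({n}), got {n_axes}")
    if normalization == "unnormalized":
        w, v = scipy.linalg.eigh(L)
    elif normalization == "random_walk":
        # generalized problem L v = w Deg v; Deg = Diag(rowsum S) = diag(L)
        w, v = scipy.linalg.eigh(L, np.diag(np.diag(L)))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if not np.isfinite(w).all():
        raise RuntimeError("eigensolver failed to converge; reduce n_axes or "
                           "increase k to densify the network")
    # exactly one zero eigenvalue on a connected component
    lam = w[1:n_axes + 1]
    vecs = _orient(v[:, 1:n_axes + 1])
    if (lam <= 0).any():
        raise RuntimeError("nonpositive eigenvalue among retained axes; the "
                           "component may be disconnected")
    coords = vecs / lam[None, :]
    return TraitSpace(ids, lam, coords)


def diffusion_distance(ts: TraitSpace, species: list[str] | None = None
                       ) -> DistanceMatrix:
    """Pairwise diffusion distances: Euclidean in the rescaled coordinates.

    ``species`` restricts the output to a subset (order preserved); species
    absent from the embedded component raise a KeyError naming them.
    """
    if species is None:
        ids = list(ts.species_ids)
        X = ts.coords
    else:
        pos = {s: i for i, s in enumerate(ts.species_ids)}
        missing = [s for s in species if s not in pos]
        if missing:
            raise KeyError(f"species not in the embedded component: {missing[:5]}")
        ids = list(species)
        X = ts.coords[[pos[s] for s in species]]
    return DistanceMatrix(ids, squareform(pdist(X)))


def infer_traits(t: AbundanceTable, k: int = 10, *, n_axes: int = 20,
                 min_occurrence: int = 5) -> TraitSpace:
    """End-to-end trait inference: filter → Spearman → trusted links → embed.

    With the defaults in place, ``k`` is the method's only tunable
    parameter.
    """
    filtered = filter_species(t, min_occurrence)
    sim = spearman_similarity(filtered)
    net = trusted_links(sim, k)
    n_axes = min(n_axes, int(net.giant_component_mask().sum()) - 1)
    return embed(net, n_axes)
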