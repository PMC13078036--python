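"""Spatial structure: contiguity weights, scaled ICAR precision, Moran's I.

The spatial prior used downstream is the BYM2 reparameterisation of the
Besag-York-Mollie model.  Its structured component is an intrinsic CAR
(ICAR) field whose precision is the graph Laplacian Q = D - A of the Queen
contiguity graph, constrained to sum to zero within each connected
component.  Q is multiplied by a scaling factor c chosen so that the
geometric mean of the constrained marginal variances equals one; the
combined random-effect standard deviation then has a single, interpretable
scale regardless of the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .lattice import AreaLattice

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "ScaledICAR",
    "queen_contiguity",
    "row_standardize",
    "scaled_icar",
    "morans_i",
]


@dataclass
class SpatialWeights:
    """Contiguity weights for ``n`` areas.

    ``pairs`` stores the undirected binary adjacency (i < j); ``style``
    selects the matrix realisation: ``binary`` (symmetric 0/1) or
    ``row_standardized`` (each row divided by its neighbour count).
    """

    n: int
    pairs: np.ndarray  # (m, 2) int, i < j
    style: Literal["binary", "row_standardized"] = "binary"
    area_ids: list[str] | None = None

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if len(pairs):
            if pairs.min() < 0 or pairs.max() >= self.n:
                raise ValueError("pair indices out of range")
            pairs = np.sort(pairs, axis=1)
            pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        self.pairs = pairs

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if len(self.pairs):
            np.add.at(deg, self.pairs[:, 0], 1)
            np.add.at(deg, self.pairs[:, 1], 1)
        return deg

    @property
    def islands(self) -> np.ndarray:
        """Indices of areas with no neighbours."""
        return np.flatnonzero(self.degrees == 0)

    def matrix(self) -> sparse.csr_matrix:
        i = np.concatenate([self.pairs[:, 0], self.pairs[:, 1]])
        j = np.concatenate([self.pairs[:, 1], self.pairs[:, 0]])
        w = np.ones(len(i), dtype=float)
        m = sparse.coo_matrix((w, (i, j)), shape=(self.n, self.n)).tocsr()
        if self.style == "row_standardized":
            deg = self.degrees.astype(float)
            inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
            m = sparse.diags(inv) @ m
        return m

    def neighbors(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {i: [] for i in range(self.n)}
        for a, b in self.pairs:
            out[int(a)].append(int(b))
            out[int(b)].append(int(a))
        return {k: sorted(v) for k, v in out.items()}

    def summary(self) -> dict:
        ncomp, _ = connected_components(self.matrix(), directed=False)
        return {
            "n": self.n,
            "n_pairs": int(len(self.pairs)),
            "style": self.style,
            "islands": [int(i) for i in self.islands],
            "n_components": int(ncomp),
        }


def queen_contiguity(lattice: AreaLattice) -> SpatialWeights:
    """Binary Queen contiguity: areas are adjacent iff their polygons share
    at least one boundary point (an edge or a single vertex).

    If the lattice carries explicit adjacency pairs they are used directly;
    otherwise contiguity is derived from the polygons with an STR-tree query.
    Isolated areas are permitted and logged.
    """
    if lattice.adjacency is not None:
        w = SpatialWeights(
            n=lattice.n, pairs=lattice.adjacency_indices(), area_ids=list(lattice.area_ids)
        )
    else:
        from shapely import STRtree

        geoms = lattice.geometries
        for aid, g in zip(lattice.area_ids, geoms):
            if g is None or g.is_empty or not g.is_valid:
                raise ValueError(f"invalid or empty geometry for area {aid!r}")
        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="intersects")
        mask = left < right
        pairs = np.stack([left[mask], right[mask]], axis=1)
        w = SpatialWeights(n=lattice.n, pairs=pairs, area_ids=list(lattice.area_ids))
    isl = w.islands
    if len(isl):
        names = [w.area_ids[i] if w.area_ids else str(i) for i in isl]
        logger.warning("queen_contiguity: %d isolated area(s): %s", len(isl), names)
    return w


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Row-standardise binary weights (each row sums to one; isolated areas
    keep an all-zero row and are logged)."""
    if w.style != "binary":
        raise ValueError("row_standardize expects binary weights")
    if len(w.islands):
        logger.warning("row_standardize: %d zero-neighbour row(s) left all-zero", len(w.islands))
    return SpatialWeights(n=w.n, pairs=w.pairs.copy(), style="row_standardized", area_ids=w.area_ids)


# ---------------------------------------------------------------------------
# Scaled ICAR precision
# ---------------------------------------------------------------------------

@dataclass
class ScaledICAR:
    """Graph-Laplacian ICAR precision, scaled per connected component.

    ``scale`` holds the per-component scaling factor c (geometric mean of the
    diagonal of the constrained generalized inverse of Q_base); Q_scaled =
    c * Q_base so the generalized marginal variance of the ICAR field is one.
    Singleton components (islands) carry no spatial information and are
    treated as pure-IID downstream.
    """

    n: int
    pairs: np.ndarray
    comp_labels: np.ndarray  # (n,) component id per area
    scale: np.ndarray  # (n_components,) scaling factor; nan for singletons
    marginal_var: np.ndarray  # (n,) constrained generalized-inverse diagonal of Q_base
    _eig: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)
    # per component: (member indices, positive eigenvalues, eigenvectors)

    @property
    def n_components(self) -> int:
        return len(self.scale)

    @property
    def islands(self) -> np.ndarray:
        sizes = np.bincount(self.comp_labels, minlength=self.n_components)
        return np.flatnonzero(sizes[self.comp_labels] == 1)

    def edge_scales(self) -> np.ndarray:
        """Scaling factor applied to each adjacency pair (its component's c)."""
        return self.scale[self.comp_labels[self.pairs[:, 0]]]

    def q_base(self) -> sparse.csr_matrix:
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        deg = np.zeros(self.n)
        np.add.at(deg, i, 1.0)
        np.add.at(deg, j, 1.0)
        rows = np.concatenate([i, j, np.arange(self.n)])
        cols = np.concatenate([j, i, np.arange(self.n)])
        vals = np.concatenate([-np.ones(2 * len(i)), deg])
        return sparse.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n)).tocsr()

    def q_scaled(self) -> sparse.csr_matrix:
        c = np.where(np.isnan(self.scale), 1.0, self.scale)
        d = sparse.diags(np.sqrt(c[self.comp_labels]))
        return (d @ self.q_base() @ d).tocsr()

    def scaled_marginal_var(self) -> np.ndarray:
        """Diagonal of the constrained generalized inverse of Q_scaled;
        geometric mean is one per (non-singleton) component by construction."""
        c = np.where(np.isnan(self.scale), 1.0, self.scale)
        return self.marginal_var / c[self.comp_labels]

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw ICAR fields with unit generalized marginal variance.

        Each component's field lives on its sum-to-zero subspace; island
        areas get exactly zero (their structure carries no information).
        Returns an array of shape (size, n).
        """
        out = np.zeros((size, self.n))
        for members, lam, vec in self._eig:
            if len(members) < 2:
                continue
            c = self.scale[self.comp_labels[members[0]]]
            z = rng.standard_normal((size, len(lam)))
            out[:, members] = z @ (vec / np.sqrt(lam * c)).T
        return out


def scaled_icar(w: SpatialWeights) -> ScaledICAR:
    """Build the scaled ICAR precision from binary contiguity weights.

    Per connected component, Q = D - A is eigendecomposed; the constrained
    generalized inverse (Moore-Penrose pseudo-inverse, whose diagonal equals
    the marginal variances under the within-component sum-to-zero
    constraint) gives the scaling factor c = geometric mean of that
    diagonal.  Zero eigenvalues are identified with a 1e-9 threshold.
    Isolated single areas are flagged for pure-IID handling and logged.
    """
    if w.style != "binary":
        raise ValueError("scaled_icar expects binary weights")
    ncomp, labels = connected_components(w.matrix(), directed=False) if w.n else (0, np.array([]))
    scale = np.full(ncomp, np.nan)
    mvar = np.full(w.n, np.nan)
    eigs: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    pair_comp = labels[w.pairs[:, 0]] if len(w.pairs) else np.array([], dtype=int)
    nbrs = w.neighbors()
    for c in range(ncomp):
        members = np.flatnonzero(labels == c)
        if len(members) == 1:
            logger.warning("scaled_icar: area %d is isolated; treated as pure IID", members[0])
            continue
        pos = {a: k for k, a in enumerate(members)}
        q = np.zeros((len(members), len(members)))
        for a in members:
            q[pos[a], pos[a]] = len(nbrs[a])
            for b in nbrs[a]:
                q[pos[a], pos[b]] = -1.0
        lam, vec = np.linalg.eigh(q)
        keep = lam > 1e-9
        if keep.sum() != len(members) - 1:
            raise ValueError(f"component {c}: Laplacian rank deficiency != 1")
        diag = ((vec[:, keep] ** 2) / lam[keep]).sum(axis=1)
        scale[c] = np.exp(np.mean(np.log(diag)))
        mvar[members] = diag
        eigs.append((members, lam[keep], vec[:, keep]))
    return ScaledICAR(
        n=w.n, pairs=w.pairs.copy(), comp_labels=labels, scale=scale, marginal_var=mvar, _eig=eigs
    )


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(
    values: np.ndarray,
    w: SpatialWeights,
    permutations: int | np.ndarray = 999,
    seed: int | None = None,
    alternative: Literal["greater", "less", "two-sided"] = "greater",
    method: Literal["permutation", "normal"] = "permutation",
) -> tuple[float, float]:
    """Moran's I with a permutation (default) or analytic-normal p-value.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values and S0 the total weight.  The permutation null shuffles area
    labels; under the null E[I] = -1/(n-1).  ``permutations`` may be an
    explicit (K, n) index array, which makes the test exactly equivariant
    under relabeling of areas (map each permutation through the relabeling).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 areas")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    if n != w.n:
        raise ValueError("values length does not match weights")
    m = w.matrix()
    s0 = m.sum()
    z = x - x.mean()
    denom = float(z @ z)
    i_obs = float(n / s0 * (z @ (m @ z)) / denom)

    if method == "normal":
        # moments under the randomization assumption
        wd = m.toarray()
        ws = 0.5 * (wd + wd.T)
        s1 = 2.0 * float((ws ** 2).sum())
        rowsums = wd.sum(axis=1) + wd.sum(axis=0)
        s2 = float((rowsums ** 2).sum())
        e_i = -1.0 / (n - 1)
        b2 = n * float((z ** 4).sum()) / denom ** 2
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2) - b2 * (
            (n * n - n) * s1 - 2 * n * s2 + 6 * s0 ** 2
        )
        var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2) - e_i ** 2
        from scipy.stats import norm

        zscore = (i_obs - e_i) / np.sqrt(var_i)
        if alternative == "greater":
            p = float(norm.sf(zscore))
        elif alternative == "less":
            p = float(norm.cdf(zscore))
        else:
            p = float(2 * norm.sf(abs(zscore)))
        return i_obs, min(p, 1.0)

    if isinstance(permutations, np.ndarray):
        perm_idx = np.asarray(permutations, dtype=np.int64)
    else:
        rng = np.random.default_rng(seed)
        perm_idx = np.stack([rng.permutation(n) for _ in range(int(permutations))])
    k_perm = len(perm_idx)
    sims = np.empty(k_perm)
    for k in range(k_perm):
        zp = z[perm_idx[k]]
        sims[k] = n / s0 * (zp @ (m @ zp)) / denom
    ge = int((sims >= i_obs).sum())
    le = int((sims <= i_obs).sum())
    if alternative == "greater":
        p = (1 + ge) / (k_perm + 1)
    elif alternative == "less":
        p = (1 + le) / (k_perm + 1)
    else:
        p = min(1.0, 2 * min((1 + ge), (1 + le)) / (k_perm + 1))
    return i_obs, float(p)
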