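"""Richness, rarefaction, unweighted UniFrac, PCoA and Ward clustering.

The beta-diversity pathway is implemented from first principles: UniFrac by
explicit branch enumeration over the feature phylogeny, principal
coordinates by Gower double-centering with the negative-eigenvalue block
retained (not discarded), and Ward linkage by Lance-Williams updates on
squared distances — so every downstream permutation statistic is exactly
reproducible from the definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountTable, PhylogeneticTree, RelAbundTable, logger


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal.

    Entries may be NaN (a pair whose distance is undefined, e.g. two empty
    communities); NaN pairs are excluded by consumers that cannot carry them.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        finite = ~np.isnan(self.values)
        sym = np.abs(self.values - self.values.T)
        if np.nanmax(sym, initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values[finite] < 0).any():
            raise ValueError("negative distances")

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PcoaResult:
    """Principal coordinates with the imaginary (negative-eigenvalue) block.

    Squared inter-sample distances decompose as the squared Euclidean
    distance in the positive block minus that in the negative block.
    """

    labels: list[str]
    eigenvalues: np.ndarray  # sorted descending, may contain negatives
    pos_coords: np.ndarray  # n x k+ coordinates on positive axes
    neg_coords: np.ndarray  # n x k- coordinates on negative axes


@dataclass
class Dendrogram:
    """Agglomerative merge sequence: (cluster_a, cluster_b, height, size).

    Clusters are named by their lexicographically smallest member label.
    """

    merges: list[tuple[str, str, float, int]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]


# ---------------------------------------------------------------------------
# richness
# ---------------------------------------------------------------------------


def richness_at_threshold(rel: RelAbundTable, threshold: float = 0.002) -> pd.Series:
    """Per-sample count of features at or above a relative-abundance threshold."""
    return (rel.data >= threshold).sum(axis=1).rename("richness")


def rarefaction_richness(
    counts: CountTable,
    depth: int | None = None,
    reps: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expected richness at a common depth by repeated subsampling.

    Each replicate subsamples ``depth`` reads without replacement (a
    multivariate hypergeometric draw) and counts distinct features; the
    estimate is the mean over replicates.  ``depth=None`` uses the minimum
    per-sample total.  Samples shallower than ``depth`` are emitted as
    missing with a warning.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    totals = counts.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    shallow = []
    for sample, row in counts.data.iterrows():
        total = int(row.sum())
        if total < depth:
            shallow.append(sample)
            out[sample] = np.nan
            continue
        colors = row.to_numpy()
        draws = rng.multivariate_hypergeometric(colors, depth, size=reps)
        out[sample] = float((draws > 0).sum(axis=1).mean())
    if shallow:
        logger.warning("samples shallower than depth %d emitted as missing: %s",
                       depth, shallow)
    return pd.Series(out, name="rarefaction_richness")


# ---------------------------------------------------------------------------
# unweighted UniFrac
# ---------------------------------------------------------------------------


def presence_sets(table: RelAbundTable | CountTable) -> dict[str, set[str]]:
    """Per-sample sets of features with a positive (post-filter) value."""
    data = table.data
    return {
        str(s): set(data.columns[data.loc[s].to_numpy() > 0])
        for s in data.index
    }


def unweighted_unifrac(
    tree: PhylogeneticTree, presence: Mapping[str, set[str]]
) -> DistanceMatrix:
    """Unweighted UniFrac by explicit branch enumeration.

    For each sample pair the distance is the branch length leading to tips
    present in exactly one sample over the branch length leading to tips
    present in at least one; a branch counts for a sample when any tip of
    its subtree is present there.  The root's own stem (which subtends all
    tips and can never be unique) is excluded from both sums.  A pair of
    two empty communities has no defined distance and is emitted as NaN.
    """
    samples = list(presence)
    tips = tree.tip_names
    unknown = sorted(set().union(*presence.values()) - tips) if samples else []
    if unknown:
        raise ValueError(f"features absent from the tree: {unknown}")

    sample_index = {s: i for i, s in enumerate(samples)}
    nodes = [n for n in tree.tree.postorder(include_self=False)]
    lengths = np.array([n.length for n in nodes], dtype=float)
    membership = np.zeros((len(nodes), len(samples)), dtype=bool)
    node_row = {id(n): i for i, n in enumerate(nodes)}
    for i, node in enumerate(nodes):  # postorder: children precede parents
        if node.is_tip():
            for s, feats in presence.items():
                membership[i, sample_index[s]] = node.name in feats
        else:
            for child in node.children:
                membership[i] |= membership[node_row[id(child)]]

    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = membership[:, i], membership[:, j]
            union = a | b
            total = lengths[union].sum()
            if total == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            unique = lengths[a ^ b].sum()
            d[i, j] = d[j, i] = unique / total
    return DistanceMatrix(samples, d)


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical scaling (Gower double-centering of -d^2/2) keeping both blocks.

    Eigenvalues are sorted descending; axes with |eigenvalue| below a
    relative tolerance are dropped.  Negative-eigenvalue axes are returned
    separately so squared distances reconstruct exactly as
    ``sum(pos diffs^2) - sum(neg diffs^2)``.
    """
    if np.isnan(d.values).any():
        raise ValueError("pcoa requires a complete distance matrix")
    n = len(d.labels)
    a = -0.5 * d.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    g = (g + g.T) / 2
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigvals).max()))
    keep = np.abs(eigvals) > tol
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    return PcoaResult(
        labels=list(d.labels),
        eigenvalues=eigvals,
        pos_coords=coords[:, eigvals > 0],
        neg_coords=coords[:, eigvals < 0],
    )


def reconstructed_squared_distances(res: PcoaResult) -> np.ndarray:
    """Squared distances implied by a PCoA embedding (pos block minus neg)."""
    def sq(coords: np.ndarray) -> np.ndarray:
        if coords.shape[1] == 0:
            return np.zeros((coords.shape[0], coords.shape[0]))
        diff = coords[:, None, :] - coords[None, :, :]
        return (diff**2).sum(axis=2)

    return sq(res.pos_coords) - sq(res.neg_coords)


# ---------------------------------------------------------------------------
# Ward hierarchical clustering
# ---------------------------------------------------------------------------


def ward_clustering(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative Ward linkage via Lance-Williams updates on squared distances.

    At each step the pair with the smallest current merge cost is joined
    (ties broken by the lexicographically smallest pair of cluster labels,
    where a cluster is labeled by its smallest member).  Heights are
    reported on the original distance scale and are non-decreasing for a
    metric input.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("ward_clustering requires at least 2 samples")
    if np.isnan(d.values).any():
        raise ValueError("ward_clustering requires a complete distance matrix")
    s = d.values.astype(float) ** 2  # squared-distance working matrix
    active = {i: (d.labels[i], 1) for i in range(n)}  # idx -> (label, size)
    merges: list[tuple[str, str, float, int]] = []
    s = s.copy()
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                li, lj = active[i][0], active[j][0]
                pair_labels = tuple(sorted((li, lj)))
                key = (s[i, j], pair_labels)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _), i, j = best
        li, si = active[i]
        lj, sj = active[j]
        height = float(np.sqrt(s[i, j]))
        a, b = sorted((li, lj))
        merges.append((a, b, height, si + sj))
        # Lance-Williams (Ward) update into slot i
        for k in active:
            if k in (i, j):
                continue
            sk = active[k][1]
            s_new = ((si + sk) * s[i, k] + (sj + sk) * s[j, k]
                     - sk * s[i, j]) / (si + sj + sk)
            s[i, k] = s[k, i] = s_new
        active[i] = (a, si + sj)
        del active[j]
    return Dendrogram(merges)
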