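"""Permutation and classical statistics over community tables and distances.

PERMANOVA, beta-dispersion and the indicator-value statistic are computed
from their definitions with label-permutation nulls; the permutation
p-value convention is (1 + #{null >= observed}) / (1 + n_perm) throughout,
so no finite test ever reports p = 0.  Fisher's exact test enumerates the
hypergeometric distribution directly, Spearman's rho is Pearson on
mid-ranks with an exact permutation p at small n, and Goodman-Kruskal tau
is the proportional reduction in Gini variation of one categorical
variable given another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import DistanceMatrix, pcoa


@dataclass
class Grouping:
    """Sample -> group label; samples with missing labels are excluded upstream."""

    labels: dict[str, str]

    @classmethod
    def from_series(cls, series: pd.Series) -> "Grouping":
        return cls({str(k): str(v) for k, v in series.dropna().items()})

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.labels.values():
            if g not in seen:
                seen.append(g)
        return seen

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.labels.values():
            out[g] = out.get(g, 0) + 1
        return out

    def restrict(self, samples: list[str]) -> "Grouping":
        return Grouping({s: self.labels[s] for s in samples if s in self.labels})


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    method: str
    status: str = "ok"
    extra: dict = field(default_factory=dict)


def _perm_p(null: np.ndarray, observed: float) -> float:
    return (1.0 + int((null >= observed - 1e-12).sum())) / (1.0 + len(null))


def _align(d: DistanceMatrix, g: Grouping) -> tuple[np.ndarray, np.ndarray, list[str]]:
    samples = [s for s in d.labels if s in g.labels]
    missing = [s for s in g.labels if s not in d.labels]
    if missing:
        raise ValueError(f"grouped samples absent from the distance matrix: {missing}")
    sub = d.subset(samples)
    labels = np.array([g.labels[s] for s in samples])
    return sub.values, labels, samples


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            block = d2[np.ix_(idx, idx)]
            ss_within += block[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: DistanceMatrix,
    g: Grouping,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """One-way PERMANOVA: pseudo-F on a distance matrix, p by label permutation.

    SS_total = sum over pairs of d^2 / N; SS_within sums each group's pair
    d^2 over its size; pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)).
    Degenerate groupings with zero within-group variation are flagged
    rather than reported as a number.
    """
    values, labels, _ = _align(d, g)
    uniq, codes = np.unique(labels, return_inverse=True)
    a, n = len(uniq), len(labels)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if n < a + 1:
        raise ValueError("PERMANOVA needs more samples than groups")
    d2 = values**2
    observed = _permanova_f(d2, codes, a)
    if not np.isfinite(observed):
        return PermutationTestResult(np.nan, np.nan, n_perm, seed, "permanova",
                                     status="degenerate: zero within-group variation")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _permanova_f(d2, rng.permutation(codes), a)
    return PermutationTestResult(
        float(observed), _perm_p(null, observed), n_perm, seed, "permanova",
        extra={"df_between": a - 1, "df_within": n - a},
    )


def pairwise_permanova(
    d: DistanceMatrix,
    g: Grouping,
    n_perm: int = 1000,
    seed: int = 0,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """PERMANOVA restricted to each pair of groups, Bonferroni-adjusted."""
    groups = sorted(g.groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    rows = []
    for k, (ga, gb) in enumerate(pairs):
        samples = [s for s, lab in g.labels.items() if lab in (ga, gb)]
        res = permanova(d, g.restrict(samples), n_perm=n_perm, seed=seed + k)
        rows.append({"group_a": ga, "group_b": gb, "pseudo_F": res.statistic,
                     "p_value": res.p_value, "status": res.status})
    frame = pd.DataFrame(rows)
    if correction == "bonferroni":
        frame["p_adjusted"] = (frame["p_value"] * len(pairs)).clip(upper=1.0)
    elif correction == "none":
        frame["p_adjusted"] = frame["p_value"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return frame


# ---------------------------------------------------------------------------
# beta dispersion (PERMDISP)
# ---------------------------------------------------------------------------


def _anova_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_between = ss_within = 0.0
    for g in range(n_groups):
        zg = z[codes == g]
        ss_between += len(zg) * (zg.mean() - grand) ** 2
        ss_within += ((zg - zg.mean()) ** 2).sum()
    if ss_within <= 0:
        return np.inf
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def beta_dispersion(
    d: DistanceMatrix,
    g: Grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.Series, PermutationTestResult]:
    """Homogeneity of multivariate dispersions on a distance matrix.

    Samples are embedded by PCoA (keeping the negative-eigenvalue block);
    each sample's dispersion is its distance to its group centroid,
    ``sqrt(max(0, d+^2 - d-^2))`` across the two blocks.  The group effect
    is a one-way ANOVA F on those distances with a label-permutation p.
    """
    values, labels, samples = _align(d, g)
    uniq, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if len(uniq) < 2:
        raise ValueError("beta_dispersion needs at least 2 groups")
    if (sizes < 2).any():
        bad = uniq[sizes < 2][0]
        raise ValueError(f"group {bad!r} has fewer than 2 samples")
    res = pcoa(DistanceMatrix(samples, values))
    pos, neg = res.pos_coords, res.neg_coords
    z = np.empty(len(samples))
    for gi in range(len(uniq)):
        idx = codes == gi
        dp2 = ((pos[idx] - pos[idx].mean(axis=0)) ** 2).sum(axis=1)
        dn2 = ((neg[idx] - neg[idx].mean(axis=0)) ** 2).sum(axis=1) \
            if neg.shape[1] else 0.0
        z[idx] = np.sqrt(np.maximum(0.0, dp2 - dn2))
    observed = _anova_f(z, codes, len(uniq))
    if not np.isfinite(observed):
        result = PermutationTestResult(np.nan, np.nan, n_perm, seed,
                                       "beta_dispersion",
                                       status="degenerate: zero within-group spread")
        return pd.Series(z, index=samples, name="dist_to_centroid"), result
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _anova_f(z, rng.permutation(codes), len(uniq))
    result = PermutationTestResult(float(observed), _perm_p(null, observed),
                                   n_perm, seed, "beta_dispersion")
    return pd.Series(z, index=samples, name="dist_to_centroid"), result


def pairwise_beta_dispersion(
    d: DistanceMatrix,
    g: Grouping,
    n_perm: int = 999,
    seed: int = 0,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Beta-dispersion test restricted to each pair of groups."""
    groups = sorted(g.groups)
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    rows = []
    for k, (ga, gb) in enumerate(pairs):
        samples = [s for s, lab in g.labels.items() if lab in (ga, gb)]
        _, res = beta_dispersion(d, g.restrict(samples), n_perm=n_perm,
                                 seed=seed + k)
        rows.append({"group_a": ga, "group_b": gb, "F": res.statistic,
                     "p_value": res.p_value, "status": res.status})
    frame = pd.DataFrame(rows)
    if correction == "bonferroni":
        frame["p_adjusted"] = (frame["p_value"] * len(pairs)).clip(upper=1.0)
    else:
        frame["p_adjusted"] = frame["p_value"]
    return frame


# ---------------------------------------------------------------------------
# indicator species analysis (IndVal on presence/absence)
# ---------------------------------------------------------------------------


def _indval_stats(incidence: np.ndarray, codes: np.ndarray,
                  n_groups: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group-size-equalized IndVal components per (feature, group).

    incidence: boolean samples x features.  Returns (A, B, stat) arrays of
    shape (n_groups, n_features).
    """
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    per_group = np.vstack([
        incidence[codes == g].sum(axis=0) for g in range(n_groups)
    ]).astype(float)
    freq = per_group / sizes[:, None]  # I_g / n_g
    denom = freq.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, freq / denom, 0.0)
    b = freq
    return a, b, np.sqrt(a * b)


def indicator_species(
    presence: Mapping[str, set[str]] | pd.DataFrame,
    g: Grouping,
    n_perm: int = 999,
    seed: int = 0,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Indicator-value analysis of presence/absence against a grouping.

    For feature f and group g: A (specificity) is the group-size-equalized
    share of f's occurrence rate falling in g, B (fidelity) is f's
    occurrence rate within g, and the indicator statistic is sqrt(A*B)
    maximized over groups.  Significance is by sample-label permutation
    with the (1+x)/(1+n) convention; features absent everywhere are
    emitted as missing.
    """
    if isinstance(presence, pd.DataFrame):
        frame = presence.astype(bool)
    else:
        features = sorted(set().union(*presence.values()))
        frame = pd.DataFrame(
            {f: [f in presence[s] for s in presence] for f in features},
            index=list(presence),
        )
    samples = [s for s in frame.index if s in g.labels]
    frame = frame.loc[samples]
    labels = np.array([g.labels[s] for s in samples])
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("indicator_species needs at least 2 groups")
    inc = frame.to_numpy(dtype=bool)
    a, b, stat = _indval_stats(inc, codes, len(uniq))
    best_idx = stat.argmax(axis=0)
    cols = np.arange(inc.shape[1])
    observed = stat[best_idx, cols]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(inc.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        _, _, stat_p = _indval_stats(inc, perm, len(uniq))
        exceed += stat_p.max(axis=0) >= observed - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    absent = ~inc.any(axis=0)
    result = pd.DataFrame({
        "best_group": uniq[best_idx],
        "A": a[best_idx, cols],
        "B": b[best_idx, cols],
        "stat": observed,
        "p_value": p,
    }, index=frame.columns)
    result.loc[absent, ["best_group"]] = pd.NA
    result.loc[absent, ["A", "B", "stat", "p_value"]] = np.nan
    n_tested = int((~absent).sum())
    if correction == "bonferroni":
        result["p_adjusted"] = (result["p_value"] * n_tested).clip(upper=1.0)
    elif correction == "holm":
        order = result.loc[~absent, "p_value"].sort_values().index
        m = len(order)
        run = np.maximum.accumulate(
            result.loc[order, "p_value"].to_numpy() * (m - np.arange(m)))
        result["p_adjusted"] = np.nan
        result.loc[order, "p_adjusted"] = np.clip(run, None, 1.0)
    elif correction == "bh":
        order = result.loc[~absent, "p_value"].sort_values().index
        m = len(order)
        ranked = result.loc[order, "p_value"].to_numpy() * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        result["p_adjusted"] = np.nan
        result.loc[order, "p_adjusted"] = np.clip(adj, None, 1.0)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return result


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by direct hypergeometric enumeration.

    Returns (p, sample odds ratio).  The p-value sums the probabilities of
    all tables with the observed margins whose probability does not exceed
    the observed table's (within a 1e-7 relative slack).  The odds ratio
    (a*d)/(b*c) is inf when b*c = 0 with a*d > 0, and NaN for an empty
    diagonal pair.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact_2x2 needs a 2x2 table of non-negative ints")
    a, b = t[0]
    c, dd = t[1]
    n = a + b + c + dd
    if n == 0:
        raise ValueError("fisher_exact_2x2 needs at least one positive margin")
    row1, col1 = a + b, a + c
    rv = sps.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = np.inf if a * dd > 0 else np.nan
    else:
        odds = (a * dd) / (b * c)
    return p, float(odds)


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p.

    rho is Pearson's correlation of mid-ranks.  The p-value uses the exact
    permutation distribution for n <= 9 and the t approximation with n-2
    degrees of freedom otherwise.  Constant input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman needs two equal-length 1-D arrays")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs at least 3 paired observations")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    if n <= 9:
        rxc = rx - rx.mean()
        count = total = 0
        obs = abs(np.dot(rxc, ry - ry.mean()))
        for perm in iter_permutations(range(n)):
            val = abs(np.dot(rxc, ry[list(perm)] - ry.mean()))
            total += 1
            if val >= obs - 1e-9:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def goodman_kruskal_tau(x, y) -> float:
    """Goodman-Kruskal tau(x -> y): proportional reduction in Gini variation.

    tau = (sum_ij n_ij^2 / n_i. - sum_j n_.j^2 / n) / (n - sum_j n_.j^2 / n);
    asymmetric in its arguments, 1 when y is a function of x, 0 when x
    carries no information about y.
    """
    x = pd.Series(x).astype(str)
    y = pd.Series(y).astype(str)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("goodman_kruskal_tau needs paired non-empty vectors")
    table = pd.crosstab(x, y).to_numpy(dtype=float)
    n = table.sum()
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    marginal = (col_tot**2).sum() / n
    with np.errstate(invalid="ignore", divide="ignore"):
        conditional = np.where(row_tot > 0,
                               (table**2).sum(axis=1) / row_tot, 0.0).sum()
    denom = n - marginal
    if denom <= 0:
        return float("nan")  # y is constant: no variation to explain
    return float((conditional - marginal) / denom)
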