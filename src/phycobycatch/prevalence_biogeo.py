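"""Culture-prevalence summaries and culture-versus-ocean comparisons.

Given presence/absence of heterotroph features across enrichment cultures
and per-ocean-site OTU tables, this module computes: taxon prevalence by
host genus with Fisher contingency tests, per-site relative abundance
normalized to non-host reads, occupancy-based distribution classes
(Cosmopolitan / Intermediate / Sparse), the rank correlation of one OTU
with combined picocyanobacterial abundance, and the above/below-200 m
shared-OTU partition test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .community_stats import fisher_exact_2x2, spearman
from .io_formats import TaxonomyTable, logger
from .synthetic_data import SiteTable


@dataclass
class DistributionClass:
    """Occupancy-based distribution label of one OTU across ocean sites."""

    otu_id: str
    label: str  # Cosmopolitan | Intermediate | Sparse
    occupancy: float
    cut_cosmopolitan: float
    cut_sparse: float
    detection_floor: float


# ---------------------------------------------------------------------------
# culture prevalence
# ---------------------------------------------------------------------------


def _taxon_presence(
    presence: Mapping[str, set[str]], tax: TaxonomyTable, rank: str
) -> pd.DataFrame:
    """Collapse feature presence to taxon presence (union over member features)."""
    taxon_of: dict[str, str] = {}
    for fid in set().union(*presence.values()) if presence else set():
        if fid not in tax.ranks.index:
            raise ValueError(f"feature {fid!r} missing from taxonomy")
        name = tax.rank_of(fid, rank)
        taxon_of[fid] = name if name else "unclassified"
    taxa = sorted(set(taxon_of.values()))
    rows = {
        sample: [any(taxon_of[f] == t for f in feats if f in taxon_of)
                 for t in taxa]
        for sample, feats in presence.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=taxa)


def prevalence(
    presence: Mapping[str, set[str]],
    tax: TaxonomyTable,
    rank: str,
    partition: Mapping[str, str],
) -> pd.DataFrame:
    """Fraction of cultures containing each taxon, overall and per partition.

    ``partition`` maps each culture to its host genus (or any two-level
    factor); every culture must be labeled.
    """
    missing = [s for s in presence if s not in partition]
    if missing:
        raise ValueError(f"cultures missing partition labels: {missing}")
    taxon_pres = _taxon_presence(presence, tax, rank)
    labels = pd.Series({s: partition[s] for s in taxon_pres.index})
    out = {"overall": taxon_pres.mean(axis=0)}
    for part in sorted(labels.unique()):
        out[part] = taxon_pres.loc[labels == part].mean(axis=0)
    return pd.DataFrame(out).rename_axis("taxon")


def prevalence_contingency(
    presence: Mapping[str, set[str]],
    tax: TaxonomyTable,
    rank: str,
    partition: Mapping[str, str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-taxon 2x2 presence tables across two partitions with Fisher tests."""
    labels = pd.Series({s: partition[s] for s in presence})
    parts = sorted(labels.unique())
    if len(parts) != 2:
        raise ValueError(f"prevalence_contingency needs exactly 2 partitions, "
                         f"got {parts}")
    taxon_pres = _taxon_presence(presence, tax, rank)
    in_a = labels == parts[0]
    rows = []
    for taxon in taxon_pres.columns:
        pres_a = int(taxon_pres.loc[in_a, taxon].sum())
        pres_b = int(taxon_pres.loc[~in_a, taxon].sum())
        abs_a = int(in_a.sum()) - pres_a
        abs_b = int((~in_a).sum()) - pres_b
        p, odds = fisher_exact_2x2([[pres_a, abs_a], [pres_b, abs_b]])
        rows.append({
            "taxon": taxon,
            f"present_{parts[0]}": pres_a, f"absent_{parts[0]}": abs_a,
            f"present_{parts[1]}": pres_b, f"absent_{parts[1]}": abs_b,
            "odds_ratio": odds, "p_value": p,
        })
    frame = pd.DataFrame(rows).set_index("taxon")
    if correction == "bonferroni":
        frame["p_adjusted"] = (frame["p_value"] * len(frame)).clip(upper=1.0)
    else:
        frame["p_adjusted"] = frame["p_value"]
    return frame


# ---------------------------------------------------------------------------
# ocean site analyses
# ---------------------------------------------------------------------------


def site_relative_abundance(sites: SiteTable) -> pd.DataFrame:
    """Per-site OTU read fractions of non-host reads.

    The denominator is ``total_reads - host_reads``; sites where it is not
    positive carry no information about heterotrophs and are emitted as
    all-missing rows with a warning.
    """
    denom = (sites.sites["total_reads"] - sites.sites["host_reads"]).astype(float)
    flagged = list(denom.index[denom <= 0])
    if flagged:
        logger.warning("sites with no non-host reads emitted as missing: %s", flagged)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = sites.otu_counts.to_numpy(dtype=float) / denom.to_numpy()[:, None]
    frac[denom.to_numpy() <= 0, :] = np.nan
    return pd.DataFrame(frac, index=sites.otu_counts.index,
                        columns=sites.otu_counts.columns)


def log10_with_floor(fractions: pd.DataFrame, floor: float = 1e-6) -> pd.DataFrame:
    """Display helper: log10 of fractions with zeros clipped to a floor."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.log10(fractions.clip(lower=floor))


def classify_distribution(
    sites: SiteTable,
    otu_id: str,
    cut_cosmopolitan: float = 0.75,
    cut_sparse: float = 0.25,
    detection_floor: float = 0.0,
) -> DistributionClass:
    """Label one OTU by the fraction of sites where it is detected.

    Occupancy is the fraction of informative sites with OTU fraction
    strictly above ``detection_floor``; labels are Cosmopolitan at or above
    ``cut_cosmopolitan``, Sparse at or below ``cut_sparse``, Intermediate
    between.
    """
    if not (0 <= cut_sparse < cut_cosmopolitan <= 1):
        raise ValueError("need 0 <= cut_sparse < cut_cosmopolitan <= 1")
    frac = site_relative_abundance(sites)[otu_id].dropna()
    if frac.empty:
        raise ValueError("no informative sites")
    occupancy = float((frac > detection_floor).mean())
    if occupancy >= cut_cosmopolitan:
        label = "Cosmopolitan"
    elif occupancy <= cut_sparse:
        label = "Sparse"
    else:
        label = "Intermediate"
    return DistributionClass(otu_id, label, occupancy,
                             cut_cosmopolitan, cut_sparse, detection_floor)


def classify_all(sites: SiteTable, **kwargs) -> pd.DataFrame:
    """classify_distribution over every OTU of a site table."""
    rows = [classify_distribution(sites, o, **kwargs).__dict__
            for o in sites.otu_ids]
    return pd.DataFrame(rows).set_index("otu_id")


def host_coupling(sites: SiteTable, otu_id: str) -> tuple[float, float]:
    """Spearman correlation of one OTU's site fractions with host abundance.

    Host abundance is the combined host-assigned read fraction per site.
    Zeros rank at the bottom as ties; a constant OTU has no defined rank
    correlation and yields (nan, nan).
    """
    frac = site_relative_abundance(sites)[otu_id]
    host = (sites.sites["host_reads"] / sites.sites["total_reads"]).astype(float)
    paired = pd.DataFrame({"otu": frac, "host": host}).dropna()
    if len(paired) < 3:
        raise ValueError("host_coupling needs at least 3 informative sites")
    return spearman(paired["otu"].to_numpy(), paired["host"].to_numpy())


def depth_partition_overlap(
    sites: SiteTable,
    culture_otus: Iterable[str],
    depth_cut: float = 200.0,
) -> tuple[np.ndarray, float, float]:
    """Do deep sites share more OTUs with cultures than surface sites?

    Sites strictly below ``depth_cut`` (the epipelagic boundary) form the
    "below" pool, sites at or above it the "above" pool (a site exactly at
    the cut counts as above).  Each pool's detected OTUs are split into
    shared (present in at least one culture) and unshared; the 2x2 table
    [[shared_below, unshared_below], [shared_above, unshared_above]] is
    tested two-sided by Fisher's exact test.
    """
    culture_set = set(culture_otus)
    frac = site_relative_abundance(sites)
    below_sites = sites.sites["depth_m"] > depth_cut
    if below_sites.all() or (~below_sites).all():
        raise ValueError(f"all sites on one side of the {depth_cut} m cut")

    def pool(mask: pd.Series) -> set[str]:
        sub = frac.loc[mask.index[mask]].fillna(0.0)
        return set(sub.columns[(sub > 0).any(axis=0)])

    below = pool(below_sites)
    above = pool(~below_sites)
    table = np.array([
        [len(below & culture_set), len(below - culture_set)],
        [len(above & culture_set), len(above - culture_set)],
    ])
    p, odds = fisher_exact_2x2(table)
    return table, p, odds
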