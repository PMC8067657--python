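"""Contamination filtering for plate-sequenced amplicon tables.

Two bespoke filters act on per-sample relative abundances:

* the **adjacency filter** zeroes a feature in a well when its relative
  abundance is less than a configured fraction (default 10%) of the maximum
  relative abundance of that feature in any adjacent well of the 96-well
  plate — the signature of PCR product bleeding between neighboring wells;
* the **abundance floor** zeroes entries below a fixed relative abundance
  (default 0.2%), a cutoff calibrated against mock communities in which no
  spurious sequence exceeded that level.

Both filters evaluate simultaneously against the input table (no in-place
sequential zeroing) and never renormalize, so one feature's removal cannot
change another's pass/fail status.  Host and organelle exclusion and
host-read normalization live here too because they share the taxonomy
plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CountTable,
    DEFAULT_HOST_SET,
    DEFAULT_ORGANELLE_SET,
    PlateLayout,
    RelAbundTable,
    TaxonomyTable,
    Well,
    PLATE_ROWS,
    PLATE_COLS,
    logger,
)


@dataclass
class FilterParams:
    """Thresholds of the decontamination filters (study defaults)."""

    adjacency_ratio: float = 0.10
    abundance_floor: float = 0.002
    adjacency_scheme: str = "edge8"
    host_set: frozenset[str] = DEFAULT_HOST_SET
    organelle_set: frozenset[str] = DEFAULT_ORGANELLE_SET

    def __post_init__(self) -> None:
        if not (0 < self.adjacency_ratio < 1):
            raise ValueError("adjacency_ratio must lie in (0,1)")
        if not (0 <= self.abundance_floor < 1):
            raise ValueError("abundance_floor must lie in [0,1)")
        if self.adjacency_scheme not in ("edge4", "edge8"):
            raise ValueError("adjacency_scheme must be 'edge4' or 'edge8'")


@dataclass
class FilterEntry:
    """One zeroed (sample, feature) cell and the rule that removed it."""

    sample_id: str
    feature_id: str
    rule: str  # "adjacency" | "floor"
    value: float
    adjacent_sample: str | None = None
    adjacent_value: float | None = None


@dataclass
class FilterReport:
    entries: list[FilterEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [e.__dict__ for e in self.entries],
            columns=["sample_id", "feature_id", "rule", "value",
                     "adjacent_sample", "adjacent_value"],
        )

    def __len__(self) -> int:
        return len(self.entries)


def to_relative_abundance(counts: CountTable) -> RelAbundTable:
    """Divide each sample's counts by its total; all-zero samples stay zero."""
    values = counts.data.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, values / totals, 0.0)
    return RelAbundTable(
        pd.DataFrame(rel, index=counts.data.index, columns=counts.data.columns)
    )


def adjacent_wells(well: Well, scheme: str = "edge8") -> set[Well]:
    """Neighbors of a well on the 8x12 grid (queen or rook adjacency)."""
    if well.row not in PLATE_ROWS or well.col not in PLATE_COLS:
        raise ValueError(f"well {well!r} outside the 8x12 grid")
    if scheme == "edge4":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif scheme == "edge8":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    else:
        raise ValueError(f"unknown adjacency scheme {scheme!r}")
    r0 = PLATE_ROWS.index(well.row)
    out = set()
    for dr, dc in offsets:
        r, c = r0 + dr, well.col + dc
        if 0 <= r < len(PLATE_ROWS) and 1 <= c <= 12:
            out.add(Well(PLATE_ROWS[r], c))
    return out


def apply_adjacency_filter(
    rel: RelAbundTable,
    layout: PlateLayout,
    params: FilterParams | None = None,
    strict: bool = False,
) -> tuple[RelAbundTable, FilterReport]:
    """Zero entries that look like leakage from an adjacent well.

    An entry is zeroed when it is positive and *strictly less than*
    ``adjacency_ratio`` times the maximum relative abundance of the same
    feature in any occupied adjacent well.  All comparisons are made against
    the input table, so the result is order-independent.  Samples absent
    from the layout pass through unfiltered (or raise in strict mode).
    """
    params = params or FilterParams()
    missing = [s for s in rel.sample_ids if s not in layout.wells]
    if missing:
        if strict:
            raise ValueError(f"samples missing from plate layout: {missing}")
        logger.warning("%d samples absent from plate layout pass unfiltered: %s",
                       len(missing), missing)

    values = rel.data.to_numpy(dtype=float)
    out = values.copy()
    report = FilterReport()
    occupied = {w: s for s, w in layout.wells.items()}
    row_of = {s: i for i, s in enumerate(rel.sample_ids)}
    for sample in rel.sample_ids:
        if sample not in layout.wells:
            continue
        neigh = [occupied[w] for w in
                 adjacent_wells(layout.wells[sample], params.adjacency_scheme)
                 if w in occupied and occupied[w] in row_of]
        if not neigh:
            continue
        block = values[[row_of[s] for s in neigh], :]
        adj_max = block.max(axis=0)
        which = block.argmax(axis=0)
        i = row_of[sample]
        mask = (values[i] > 0) & (values[i] < params.adjacency_ratio * adj_max)
        out[i, mask] = 0.0
        for j in np.flatnonzero(mask):
            report.entries.append(FilterEntry(
                sample, rel.feature_ids[j], "adjacency", float(values[i, j]),
                adjacent_sample=neigh[which[j]],
                adjacent_value=float(adj_max[j]),
            ))
    filtered = RelAbundTable(
        pd.DataFrame(out, index=rel.data.index, columns=rel.data.columns))
    return filtered, report


def apply_abundance_floor(
    rel: RelAbundTable, params: FilterParams | None = None
) -> tuple[RelAbundTable, FilterReport]:
    """Zero entries strictly below the floor; entries exactly at it are kept."""
    params = params or FilterParams()
    values = rel.data.to_numpy(dtype=float)
    mask = (values > 0) & (values < params.abundance_floor)
    out = np.where(mask, 0.0, values)
    report = FilterReport()
    for i, j in np.argwhere(mask):
        report.entries.append(FilterEntry(
            rel.sample_ids[i], rel.feature_ids[j], "floor", float(values[i, j])))
    filtered = RelAbundTable(
        pd.DataFrame(out, index=rel.data.index, columns=rel.data.columns))
    return filtered, report


def exclude_features(
    counts: CountTable,
    tax: TaxonomyTable,
    which: str = "both",
) -> tuple[CountTable, pd.DataFrame]:
    """Drop host and/or organelle features, returning per-sample removed totals.

    The per-class removed read totals (columns ``host`` / ``organelle``) feed
    host-read normalization downstream.
    """
    if which not in ("host", "organelle", "both"):
        raise ValueError("which must be 'host', 'organelle' or 'both'")
    missing = [f for f in counts.feature_ids if f not in tax.ranks.index]
    if missing:
        raise ValueError(f"features missing from taxonomy: {missing}")
    feats = pd.Index(counts.feature_ids)
    host_mask = tax.is_host.reindex(feats).to_numpy()
    org_mask = tax.is_organelle.reindex(feats).to_numpy()
    drop = np.zeros(len(feats), dtype=bool)
    if which in ("host", "both"):
        drop |= host_mask
    if which in ("organelle", "both"):
        drop |= org_mask
    removed = pd.DataFrame({
        "host": counts.data.loc[:, feats[host_mask]].sum(axis=1),
        "organelle": counts.data.loc[:, feats[org_mask]].sum(axis=1),
    })
    kept = CountTable(counts.data.loc[:, feats[~drop]].copy())
    return kept, removed


def host_normalize(
    het_counts: CountTable, host_totals: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Divide heterotroph counts by per-sample host reads.

    Samples with zero host reads are emitted as all-missing rows (never
    infinities) and returned in the flagged list.
    """
    host = host_totals.reindex(het_counts.data.index)
    if host.isna().any():
        missing = list(host.index[host.isna()])
        raise ValueError(f"samples missing host totals: {missing}")
    flagged = list(host.index[host <= 0])
    if flagged:
        logger.warning("samples with zero host reads flagged as missing: %s", flagged)
    denom = host.to_numpy(dtype=float)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(denom > 0, het_counts.counts / denom, np.nan)
    return (
        pd.DataFrame(ratios, index=het_counts.data.index,
                     columns=het_counts.data.columns),
        flagged,
    )


def calibrate_floor(observed, design) -> tuple[float, pd.DataFrame]:
    """Recommend an abundance floor from mock-community sequencing.

    The recommended floor is the maximum relative abundance reached by any
    feature *not* in the mock design, across all replicates (0 when no such
    feature is observed).  The report lists every non-member feature with
    its maximum relative abundance.
    """
    members = set(design.member_ids)
    if not members & set(observed.feature_ids):
        raise ValueError("no overlap between observed features and design members")
    rel = to_relative_abundance(observed)
    non_members = [f for f in rel.feature_ids if f not in members]
    if not non_members:
        return 0.0, pd.DataFrame(columns=["feature_id", "max_rel_abundance"])
    max_rel = rel.data[non_members].max(axis=0)
    report = (
        max_rel.rename("max_rel_abundance").rename_axis("feature_id")
        .reset_index().sort_values("max_rel_abundance", ascending=False,
                                   ignore_index=True)
    )
    return float(max_rel.max()), report


def decontaminate(
    counts: CountTable,
    layout: PlateLayout,
    params: FilterParams | None = None,
    order: str = "adjacency-first",
) -> tuple[RelAbundTable, FilterReport]:
    """Run both filters in the configured order on a raw count table."""
    params = params or FilterParams()
    rel = to_relative_abundance(counts)
    if order == "adjacency-first":
        rel, rep1 = apply_adjacency_filter(rel, layout, params)
        rel, rep2 = apply_abundance_floor(rel, params)
    elif order == "floor-first":
        rel, rep1 = apply_abundance_floor(rel, params)
        rel, rep2 = apply_adjacency_filter(rel, layout, params)
    else:
        raise ValueError("order must be 'adjacency-first' or 'floor-first'")
    return rel, FilterReport(rep1.entries + rep2.entries)
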