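"""Simulators for plates, mock communities, trees and ocean site tables.

These generate data with the statistical structure the analysis assumes —
wells dominated by a single cyanobacterial host with a heterotroph tail and
cross-well leakage, equimolar / two-fold dilution-series mock communities,
and ocean transect site tables with cosmopolitan / intermediate / sparse
occupancy archetypes plus one host-coupled taxon — together with the ground
truth needed for filter-performance and parameter-recovery tests.

All simulators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import skbio

from .io_formats import (
    CountTable,
    PlateLayout,
    PhylogeneticTree,
    TaxonomyTable,
    TAXONOMY_RANKS,
    Well,
    PLATE_ROWS,
)


# ---------------------------------------------------------------------------
# parameter containers and ground truth
# ---------------------------------------------------------------------------


@dataclass
class PlateSimParams:
    """Controls for the 96-well plate simulator.

    Each well holds one host feature at a fraction drawn from
    ``host_fraction_range`` plus a log-normal mixture of heterotrophs from a
    shared pool; an ordered adjacent pair (receiver, source) leaks a fraction
    ``eps`` of the source well's amplicon pool into the receiver.
    """

    n_wells: int = 48
    pool_size: int = 60
    members_per_well: tuple[int, int] = (4, 12)
    host_fraction_range: tuple[float, float] = (0.5, 0.95)
    abundance_shape: float = 1.5  # log-normal sigma of heterotroph proportions
    leakage_range: tuple[float, float] = (0.001, 0.02)
    depth_range: tuple[int, int] = (50_000, 150_000)
    adjacency_scheme: str = "edge8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells > 96 or self.n_wells < 1:
            raise ValueError(f"n_wells must be in 1..96, got {self.n_wells}")
        if self.members_per_well[1] > self.pool_size:
            raise ValueError("members_per_well exceeds pool_size")
        lo, hi = self.leakage_range
        if not (0 <= lo <= hi < 0.5):
            raise ValueError("leakage_range must lie within [0, 0.5)")
        if self.depth_range[0] < 1:
            raise ValueError("depth_range must be positive")
        if not (0 < self.host_fraction_range[0] <= self.host_fraction_range[1] < 1):
            raise ValueError("host_fraction_range must lie within (0,1)")


@dataclass
class ContaminantEntry:
    """One expected cross-well contaminant: a foreign feature leaked into a well."""

    receiver: str
    source: str
    feature: str
    expected_proportion: float


@dataclass
class GroundTruth:
    """What the simulator actually planted, for recovery tests."""

    true_members: dict[str, dict[str, float]] = field(default_factory=dict)
    contaminants: list[ContaminantEntry] = field(default_factory=list)
    leakage: dict[tuple[str, str], float] = field(default_factory=dict)
    expected_proportions: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class MockDesign:
    """A defined mixture of known strains used to calibrate detection floors."""

    member_ids: tuple[str, ...] = tuple(f"Mock{i:02d}" for i in range(1, 12))
    scheme: Literal["equimolar", "twofold_series"] = "equimolar"
    replicates: int = 3

    def intended_proportions(self) -> np.ndarray:
        """Per-member intended proportion (identical across replicates)."""
        m = len(self.member_ids)
        if self.scheme == "equimolar":
            return np.full(m, 1.0 / m)
        weights = 2.0 ** np.arange(m)[::-1]  # most concentrated first
        return weights / weights.sum()

    def max_min_ratio(self) -> float:
        p = self.intended_proportions()
        return float(p.max() / p.min())


@dataclass
class SiteSimParams:
    """Controls for the ocean transect site-table simulator."""

    n_sites: int = 500
    n_otus: int = 60
    archetype_fractions: tuple[float, float, float] = (0.2, 0.3, 0.5)
    occupancy_probs: tuple[float, float, float] = (0.9, 0.5, 0.05)
    coupling_rho: float = 0.3
    depth_max_m: float = 5000.0
    surface_fraction: float = 0.6  # fraction of sites in the epipelagic (<200 m)
    reads_per_site: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        c, i, s = self.occupancy_probs
        if not (c > i > s):
            raise ValueError("occupancy probabilities must be ordered cosmo > int > sparse")
        if abs(sum(self.archetype_fractions) - 1) > 1e-9:
            raise ValueError("archetype_fractions must sum to 1")
        if not (-1 <= self.coupling_rho <= 1):
            raise ValueError("coupling_rho must lie in [-1, 1]")


@dataclass
class SiteTable:
    """Per-ocean-site OTU counts plus host-assigned and total read counts."""

    sites: pd.DataFrame  # index site_id; columns latitude, longitude, depth_m,
    #                      host_reads, total_reads
    otu_counts: pd.DataFrame  # index site_id; columns otu ids

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.otu_counts.index):
            raise ValueError("sites and otu_counts must share the same site index")
        assigned = self.sites["host_reads"] + self.otu_counts.sum(axis=1)
        if (assigned > self.sites["total_reads"]).any():
            bad = self.sites.index[assigned > self.sites["total_reads"]][0]
            raise ValueError(f"site {bad!r}: host + OTU reads exceed total reads")
        if (self.sites["depth_m"] < 0).any():
            raise ValueError("negative site depth")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.otu_counts.columns)


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------


def _well_order(n_wells: int) -> list[Well]:
    wells = [Well(r, c) for r in PLATE_ROWS for c in range(1, 13)]
    return wells[:n_wells]


def simulate_plate(
    params: PlateSimParams,
) -> tuple[CountTable, PlateLayout, TaxonomyTable, GroundTruth]:
    """Simulate a plate of enrichment cultures with cross-well leakage.

    Each well w receives the expected composition
    ``(1 - sum(eps)) * own mixture + sum over adjacent wells eps * their mixture``
    and counts are drawn multinomially at the well's sequencing depth.
    """
    from .decontam import adjacent_wells  # local import avoids a cycle

    rng = np.random.default_rng(params.seed)
    wells = _well_order(params.n_wells)
    samples = [f"S_{w.label}" for w in wells]
    layout = PlateLayout(dict(zip(samples, wells)))
    pool = [f"Het{i:04d}" for i in range(1, params.pool_size + 1)]
    hosts = [f"Host_{w.label}" for w in wells]
    features = hosts + pool

    # true per-well mixtures over the full feature axis (host + heterotrophs)
    true_prop = pd.DataFrame(0.0, index=samples, columns=features)
    truth = GroundTruth()
    lo, hi = params.members_per_well
    for sample, well, host in zip(samples, wells, hosts):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(pool, size=k, replace=False)
        raw = rng.lognormal(mean=0.0, sigma=params.abundance_shape, size=k)
        het = raw / raw.sum()
        host_frac = rng.uniform(*params.host_fraction_range)
        true_prop.loc[sample, host] = host_frac
        true_prop.loc[sample, members] = (1 - host_frac) * het
        truth.true_members[sample] = {
            host: float(host_frac),
            **{m: float(v) for m, v in zip(members, (1 - host_frac) * het)},
        }

    # leakage: one epsilon per ordered adjacent (receiver, source) pair
    occupied = {w: s for s, w in layout.wells.items()}
    expected = true_prop.copy()
    eps_lo, eps_hi = params.leakage_range
    for sample, well in zip(samples, wells):
        neighbors = [occupied[w] for w in adjacent_wells(well, params.adjacency_scheme)
                     if w in occupied]
        eps = rng.uniform(eps_lo, eps_hi, size=len(neighbors))
        expected.loc[sample] = (1 - eps.sum()) * true_prop.loc[sample]
        for e, src in zip(eps, neighbors):
            truth.leakage[(sample, src)] = float(e)
            expected.loc[sample] += e * true_prop.loc[src]
            for feat, p in truth.true_members[src].items():
                if feat not in truth.true_members[sample]:
                    prior = next(
                        (c for c in truth.contaminants
                         if c.receiver == sample and c.feature == feat), None)
                    if prior is None:
                        truth.contaminants.append(
                            ContaminantEntry(sample, src, feat, float(e * p)))
                    else:
                        prior.expected_proportion += float(e * p)

    depths = rng.integers(params.depth_range[0], params.depth_range[1] + 1,
                          size=len(samples))
    counts = np.vstack([
        rng.multinomial(d, p / p.sum())
        for d, p in zip(depths, expected.to_numpy())
    ])
    table = CountTable(pd.DataFrame(counts, index=samples, columns=features))

    ranks = pd.DataFrame("", index=features, columns=list(TAXONOMY_RANKS))
    ranks["kingdom"] = "Bacteria"
    host_genus = np.where(rng.random(len(hosts)) < 0.5, "Prochlorococcus",
                          "Synechococcus")
    ranks.loc[hosts, "genus"] = host_genus
    ranks.loc[hosts, "phylum"] = "Cyanobacteria"
    ranks.loc[pool, "phylum"] = "Proteobacteria"
    tax = TaxonomyTable(ranks)
    truth.expected_proportions = expected
    return table, layout, tax, truth


# ---------------------------------------------------------------------------
# mock community simulation
# ---------------------------------------------------------------------------


def simulate_mock(
    design: MockDesign,
    depth: int = 113_602,
    contaminant_max_rel: float = 0.0015,
    n_contaminants: int = 3,
    seed: int = 0,
) -> tuple[CountTable, GroundTruth]:
    """Sequence a mock community with optional low-level spurious features.

    Per replicate, counts are multinomial over the intended members plus
    ``n_contaminants`` injected spurious features, each with expected
    relative abundance at most ``contaminant_max_rel``.
    """
    if not (0 <= contaminant_max_rel < 0.05):
        raise ValueError("contaminant_max_rel must lie in [0, 0.05)")
    rng = np.random.default_rng(seed)
    member_p = design.intended_proportions()
    if contaminant_max_rel == 0:
        n_contaminants = 0
    contaminant_ids = [f"Contam{i:02d}" for i in range(1, n_contaminants + 1)]
    features = list(design.member_ids) + contaminant_ids
    samples = [f"{design.scheme}_rep{r}" for r in range(1, design.replicates + 1)]

    truth = GroundTruth()
    rows = []
    for sample in samples:
        # each replicate draws its own contaminant levels below the cap
        cont_p = rng.uniform(0, contaminant_max_rel, size=n_contaminants)
        p = np.concatenate([member_p * (1 - cont_p.sum()), cont_p])
        rows.append(rng.multinomial(depth, p))
        truth.true_members[sample] = dict(zip(design.member_ids, member_p))
        for cid, cp in zip(contaminant_ids, cont_p):
            truth.contaminants.append(
                ContaminantEntry(sample, "injected", cid, float(cp)))
    table = CountTable(pd.DataFrame(rows, index=samples, columns=features))
    truth.extra["intended_proportions"] = dict(zip(design.member_ids, member_p))
    return table, truth


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(feature_ids: list[str], seed: int = 0) -> PhylogeneticTree:
    """Random coalescent-style rooted binary tree with Exp(1) branch lengths."""
    if len(feature_ids) < 2:
        raise ValueError("need at least 2 features to build a tree")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("feature ids must be unique")
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=str(f), length=float(rng.exponential()))
             for f in feature_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = skbio.TreeNode(length=float(rng.exponential()),
                                children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]
    root.length = 0.0
    return PhylogeneticTree(root)


# ---------------------------------------------------------------------------
# ocean site simulation
# ---------------------------------------------------------------------------

ARCHETYPES = ("Cosmopolitan", "Intermediate", "Sparse")


def simulate_sites(params: SiteSimParams) -> tuple[SiteTable, GroundTruth]:
    """Simulate ocean transect site tables with occupancy archetypes.

    OTUs are assigned Cosmopolitan / Intermediate / Sparse archetypes with
    the configured site-occupancy probabilities.  One designated OTU (always
    an extra, occupying every site) has its underlying abundance coupled to
    the combined picocyanobacterial host abundance through a Gaussian copula
    calibrated so that the *Spearman* correlation of the two latent scales
    equals ``coupling_rho``.
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.n_sites, params.n_otus
    site_ids = [f"Site{i:04d}" for i in range(1, n + 1)]

    # depths: surface-weighted mixture, 0-5000 m
    surface = rng.random(n) < params.surface_fraction
    depths = np.where(
        surface,
        rng.uniform(0, 200, size=n),
        np.exp(rng.uniform(np.log(200), np.log(params.depth_max_m), size=n)),
    )
    lats = rng.uniform(-60, 60, size=n)
    lons = rng.uniform(-180, 180, size=n)

    # archetype assignment
    counts_per = np.floor(np.asarray(params.archetype_fractions) * m).astype(int)
    counts_per[-1] = m - counts_per[:-1].sum()
    archetype = np.repeat(ARCHETYPES, counts_per)
    otu_ids = [f"OTU{i:04d}" for i in range(1, m + 1)]
    occ_prob = dict(zip(ARCHETYPES, params.occupancy_probs))

    # latent host abundance and the copula-coupled OTU
    z_host = rng.standard_normal(n)
    rho_gauss = 2.0 * np.sin(np.pi * params.coupling_rho / 6.0)  # Spearman -> Pearson
    z_otu = rho_gauss * z_host + np.sqrt(1 - rho_gauss**2) * rng.standard_normal(n)
    host_frac = 0.05 + 0.30 / (1.0 + np.exp(-z_host))  # host share of site reads

    # relative weights of ordinary OTUs among non-host reads
    occupied = rng.random((n, m)) < np.array([occ_prob[a] for a in archetype])
    weights = np.where(occupied, rng.lognormal(0.0, 1.0, size=(n, m)), 0.0)
    coupled_id = "OTU_coupled"
    coupled_w = np.exp(0.8 * z_otu)  # monotone in the latent scale, always present
    other_w = rng.lognormal(2.0, 0.5, size=n)  # unassigned background reads

    all_w = np.column_stack([weights, coupled_w, other_w])
    het_frac = (1 - host_frac)[:, None] * all_w / all_w.sum(axis=1, keepdims=True)
    p = np.column_stack([host_frac, het_frac])
    draws = np.vstack([rng.multinomial(params.reads_per_site, row) for row in p])

    otu_counts = pd.DataFrame(
        draws[:, 1:1 + m + 1], index=site_ids, columns=otu_ids + [coupled_id]
    )
    sites = pd.DataFrame(
        {
            "latitude": lats,
            "longitude": lons,
            "depth_m": depths,
            "host_reads": draws[:, 0],
            "total_reads": params.reads_per_site,
        },
        index=site_ids,
    )
    truth = GroundTruth()
    truth.extra["archetype"] = dict(zip(otu_ids, archetype))
    truth.extra["coupled_otu"] = coupled_id
    truth.extra["coupling_rho"] = params.coupling_rho
    truth.extra["occupancy"] = {
        oid: float(occupied[:, k].mean()) for k, oid in enumerate(otu_ids)
    }
    return SiteTable(sites, otu_counts), truth
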