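"""Sequence preparation and greedy centroid OTU clustering.

Amplicon features from different studies span nested primer regions, so
before clustering they are primer-trimmed, optionally truncated to a common
length, and dereplicated.  Clustering is greedy centroid clustering at a
fixed identity threshold (default 97%): sequences are visited in decreasing
abundance and join the first centroid they match, else found a new one —
the convention of the standard centroid-clustering tools.

Pairwise identity comes from a global, end-gap-aware alignment
(match +5, mismatch -4, gap open -10, gap extend -1 by default); identity is
matching columns over alignment columns with terminal-gap columns excluded,
which handles amplicons nested inside longer ones.  ``N`` never counts as a
match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

from Bio import Align

from .io_formats import logger


@dataclass
class SequenceSet:
    """Nucleotide sequences keyed by feature id, with optional abundances."""

    sequences: dict[str, str]
    abundances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for feature {fid!r}")
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"feature {fid!r}: invalid characters {sorted(bad)}")
        self.sequences = {f: s.upper() for f, s in self.sequences.items()}
        for fid in self.abundances:
            if fid not in self.sequences:
                raise ValueError(f"abundance given for unknown feature {fid!r}")

    def abundance(self, fid: str) -> float:
        return self.abundances.get(fid, 1.0)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class AlignScoring:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


@dataclass
class OtuMap:
    """Feature -> OTU assignment from greedy clustering.

    Centroids map to themselves; every member has identity >= threshold to
    its centroid (verifiable post hoc against ``pairwise_identity``).
    """

    threshold: float
    centroid_of: dict[str, str]  # feature_id -> centroid feature_id

    @property
    def otu_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.centroid_of.values():
            if c not in seen:
                seen.append(c)
        return seen

    def members(self, centroid: str) -> list[str]:
        return [f for f, c in self.centroid_of.items() if c == centroid]

    def n_otus(self) -> int:
        return len(set(self.centroid_of.values()))


def trim_primers(seqs: SequenceSet, n_bases: int) -> SequenceSet:
    """Remove the first ``n_bases`` of every sequence (primer region).

    Sequences that become empty are dropped with a warning.
    """
    if n_bases < 0:
        raise ValueError("n_bases must be non-negative")
    out, ab = {}, {}
    dropped = []
    for fid, seq in seqs.sequences.items():
        trimmed = seq[n_bases:]
        if trimmed:
            out[fid] = trimmed
            if fid in seqs.abundances:
                ab[fid] = seqs.abundances[fid]
        else:
            dropped.append(fid)
    if dropped:
        logger.warning("trim_primers dropped %d sequences shorter than %d bases: %s",
                       len(dropped), n_bases, dropped)
    return SequenceSet(out, ab)


def trim_to_common_length(seqs: SequenceSet) -> SequenceSet:
    """Truncate every sequence to the minimum length present."""
    if not seqs.sequences:
        raise ValueError("empty sequence set")
    n = min(len(s) for s in seqs.sequences.values())
    return SequenceSet(
        {f: s[:n] for f, s in seqs.sequences.items()}, dict(seqs.abundances))


def dereplicate(seqs: SequenceSet) -> SequenceSet:
    """Collapse identical sequence strings, summing abundances.

    The representative id of each group is the lexicographically smallest
    member id.
    """
    groups: dict[str, list[str]] = {}
    for fid, seq in seqs.sequences.items():
        groups.setdefault(seq, []).append(fid)
    out, ab = {}, {}
    for seq, members in groups.items():
        rep = min(members)
        out[rep] = seq
        ab[rep] = sum(seqs.abundance(m) for m in members)
    return SequenceSet(out, ab)


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # free end gaps: nested amplicons should not be penalized for overhangs
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # older attribute spelling
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def pairwise_identity(
    s1: str,
    s2: str,
    scoring: AlignScoring | None = None,
    definition: str = "exclude_terminal_gaps",
) -> float:
    """Fraction of identical columns in a global pairwise alignment.

    ``definition`` selects the denominator: ``exclude_terminal_gaps``
    (default; alignment columns between the first and last column where
    both sequences have a residue), ``include_terminal_gaps`` (all
    alignment columns), or ``shorter_sequence`` (length of the shorter
    input).  Symmetric in its arguments.
    """
    if not s1 or not s2:
        raise ValueError("pairwise_identity requires non-empty sequences")
    s1, s2 = s1.upper(), s2.upper()
    aligner = _make_aligner(scoring or AlignScoring())
    aln = aligner.align(s1, s2)[0]
    a, b = str(aln[0]), str(aln[1])
    shared = [i for i in range(len(a)) if a[i] != "-" and b[i] != "-"]
    if not shared:
        # sequences so dissimilar the optimal alignment never pairs residues
        return 0.0
    first = shared[0]
    last = shared[-1]
    core = range(first, last + 1)
    matches = sum(1 for i in core
                  if a[i] == b[i] and a[i] not in ("-", "N"))
    if definition == "exclude_terminal_gaps":
        denom = len(core)
    elif definition == "include_terminal_gaps":
        denom = len(a)
    elif definition == "shorter_sequence":
        denom = min(len(s1), len(s2))
    else:
        raise ValueError(f"unknown identity definition {definition!r}")
    return matches / denom if denom else 0.0


def _cluster_order(seqs: SequenceSet) -> list[str]:
    # decreasing abundance; ties broken longer-first, then lexicographic id
    return sorted(
        seqs.sequences,
        key=lambda f: (-seqs.abundance(f), -len(seqs.sequences[f]), f),
    )


def greedy_cluster(
    seqs: SequenceSet,
    threshold: float = 0.97,
    scoring: AlignScoring | None = None,
    definition: str = "exclude_terminal_gaps",
) -> OtuMap:
    """Greedy first-fit centroid clustering at a fixed identity threshold.

    Sequences are processed in decreasing abundance (ties: longer first,
    then lexicographic id); each joins the first existing centroid, in
    founding order, with identity >= threshold, else founds a new centroid.
    Fully deterministic and independent of input dict ordering.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    centroids: list[str] = []
    assignment: dict[str, str] = {}
    for fid in _cluster_order(seqs):
        seq = seqs.sequences[fid]
        for cent in centroids:
            if pairwise_identity(seq, seqs.sequences[cent], scoring,
                                 definition) >= threshold:
                assignment[fid] = cent
                break
        else:
            centroids.append(fid)
            assignment[fid] = fid
    return OtuMap(threshold, assignment)


def shared_otus(
    otu_map: OtuMap, dataset_of: Mapping[str, str | Iterable[str]]
) -> tuple[dict[frozenset, int], dict[str, int]]:
    """Count OTUs whose members span each exact subset of datasets.

    Returns (subset -> OTU count, dataset -> total OTUs containing it); the
    subset counts partition the OTUs, so inclusion-exclusion over them
    reproduces the per-dataset totals.
    """
    spans: dict[str, set[str]] = {}
    for fid, cent in otu_map.centroid_of.items():
        if fid not in dataset_of:
            raise ValueError(f"feature {fid!r} has no dataset label")
        labels = dataset_of[fid]
        labels = {labels} if isinstance(labels, str) else set(labels)
        if not labels:
            raise ValueError(f"feature {fid!r} has an empty dataset label set")
        spans.setdefault(cent, set()).update(labels)
    by_subset: dict[frozenset, int] = {}
    totals: dict[str, int] = {}
    for span in spans.values():
        key = frozenset(span)
        by_subset[key] = by_subset.get(key, 0) + 1
        for d in span:
            totals[d] = totals.get(d, 0) + 1
    return by_subset, totals
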