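"""Readers, writers and validated containers for every on-disk artifact.

All tabular artifacts are plain text (TSV/CSV), sequences are FASTA, trees
are newick and configuration is flat JSON.  Readers validate strictly and
raise :class:`FormatError` with file coordinates rather than coercing
malformed input; writers emit a canonical dialect so that
``write(read(x))`` round-trips byte-identically.
"""

from __future__ import annotations

import json
import logging
import re
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("phycobycatch")

#: Genera whose reads are the cultured cyanobacterial host.
DEFAULT_HOST_SET = frozenset({"Prochlorococcus", "Synechococcus"})
#: Lineage labels marking organellar 16S sequences.
DEFAULT_ORGANELLE_SET = frozenset({"mitochondria", "chloroplast"})

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

COUNT_TABLE_HEADER = "#phycobycatch count-table v1"

PLATE_ROWS = string.ascii_uppercase[:8]  # A..H
PLATE_COLS = range(1, 13)  # 1..12


class FormatError(ValueError):
    """Malformed input file; the message carries file coordinates."""


def configure_logging(level: str = "INFO") -> None:
    """Set up the package logger with a plain stderr handler (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Every tunable threshold of the pipeline, with the study defaults.

    Stored on disk as a flat JSON object so that a run is fully described
    by one small text file plus a seed.
    """

    adjacency_ratio: float = 0.10
    abundance_floor: float = 0.002
    adjacency_scheme: str = "edge8"
    identity_threshold: float = 0.97
    n_permutations: int = 1000
    cut_cosmopolitan: float = 0.75
    cut_sparse: float = 0.25
    depth_cut_m: float = 200.0
    seed: int = 0
    host_set: tuple[str, ...] = tuple(sorted(DEFAULT_HOST_SET))
    organelle_set: tuple[str, ...] = tuple(sorted(DEFAULT_ORGANELLE_SET))

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("host_set", "organelle_set"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def save(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# count and relative-abundance tables
# ---------------------------------------------------------------------------


def _check_axis_labels(labels: Iterable[str], axis: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {axis} label {lab!r}")
        seen.add(lab)
    return labels


@dataclass
class CountTable:
    """Integer read counts, samples as rows and features as columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axis_labels(self.data.index, "sample")
        _check_axis_labels(self.data.columns, "feature")
        values = self.data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                bad = np.argwhere(values != np.floor(values))
                if bad.size:
                    i, j = bad[0]
                    raise FormatError(
                        f"non-integer count {values[i, j]!r} at sample "
                        f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
                    )
                self.data = self.data.astype(np.int64)
                values = self.data.to_numpy()
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise FormatError(
                    f"negative count {values[i, j]} at sample "
                    f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)


@dataclass
class RelAbundTable:
    """Per-sample relative abundances on the same axes as a CountTable.

    Before filtering each row sums to 1 (all-zero rows permitted); filtered
    tables are never renormalized, so rows may sum to less than 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axis_labels(self.data.index, "sample")
        _check_axis_labels(self.data.columns, "feature")
        values = self.data.to_numpy(dtype=float)
        if values.size:
            if (values < 0).any() or (values > 1).any():
                i, j = np.argwhere((values < 0) | (values > 1))[0]
                raise FormatError(
                    f"relative abundance {values[i, j]} outside [0,1] at sample "
                    f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
                )
            sums = values.sum(axis=1)
            if (sums > 1 + 1e-9).any():
                bad = self.data.index[int(np.argmax(sums))]
                raise FormatError(f"row sum exceeds 1 for sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty table")
    header = lines[0].split("\t")
    if len(header) < 1:
        raise FormatError(f"{path}: missing header")
    feature_ids = header[1:]
    rows, index = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
            )
        index.append(parts[0])
        rows.append(parts[1:])
    frame = pd.DataFrame(rows, index=index, columns=feature_ids)
    return frame


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (header: feature ids; first column: sample ids)."""
    path = Path(path)
    frame = _read_table(path)
    try:
        dup = frame.columns[frame.columns.duplicated()]
        if len(dup):
            raise FormatError(f"{path}: duplicate feature label {dup[0]!r}")
        dup = frame.index[frame.index.duplicated()]
        if len(dup):
            raise FormatError(f"{path}: duplicate sample label {dup[0]!r}")
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy())
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"{path}: non-numeric cell {frame.iat[i, j]!r} at sample "
                f"{frame.index[i]!r}, feature {frame.columns[j]!r}"
            )
        return CountTable(numeric)
    except FormatError:
        raise
    except ValueError as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: {exc}") from exc


def write_count_table(table: CountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COUNT_TABLE_HEADER + "\n")
        fh.write("sample_id\t" + "\t".join(table.feature_ids) + "\n")
        for sample, row in table.data.iterrows():
            fh.write(str(sample) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_rel_abund_table(table: RelAbundTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(table.feature_ids) + "\n")
        for sample, row in table.data.iterrows():
            fh.write(str(sample) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_rel_abund_table(path: str | Path) -> RelAbundTable:
    frame = _read_table(path).apply(pd.to_numeric)
    return RelAbundTable(frame.astype(float))


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------


class Well(NamedTuple):
    """One well of the 96-well plate: row letter A..H, column 1..12."""

    row: str
    col: int

    @property
    def label(self) -> str:
        return f"{self.row}{self.col}"


_WELL_RE = re.compile(r"^([A-Ha-h])0*([1-9][0-9]?)$")


def parse_well(text: str) -> Well:
    """Parse a well label case-insensitively; ``A01`` normalizes to ``A1``."""
    m = _WELL_RE.match(text.strip())
    if not m:
        raise FormatError(f"well label {text!r} is not inside the 8x12 grid A1..H12")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > 12:
        raise FormatError(f"well label {text!r} is not inside the 8x12 grid A1..H12")
    return Well(row, col)


@dataclass
class PlateLayout:
    """Injective mapping of sample ids to 96-well plate positions."""

    wells: dict[str, Well]

    def __post_init__(self) -> None:
        seen: dict[Well, str] = {}
        for sample, well in self.wells.items():
            if well.row not in PLATE_ROWS or well.col not in PLATE_COLS:
                raise FormatError(f"sample {sample!r}: well {well.label} outside grid")
            if well in seen:
                raise FormatError(
                    f"well {well.label} assigned to both {seen[well]!r} and {sample!r}"
                )
            seen[well] = sample

    def sample_at(self, well: Well) -> str | None:
        for sample, w in self.wells.items():
            if w == well:
                return sample
        return None

    def occupied(self) -> dict[Well, str]:
        return {w: s for s, w in self.wells.items()}


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Read a two-column CSV ``sample_id,well``."""
    path = Path(path)
    wells: dict[str, Well] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if lineno == 1 and parts[0] == "sample_id":
                continue
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'sample_id,well'")
            sample, well_text = parts[0].strip(), parts[1]
            if sample in wells:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            try:
                wells[sample] = parse_well(well_text)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return PlateLayout(wells)


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id,well\n")
        for sample, well in layout.wells.items():
            fh.write(f"{sample},{well.label}\n")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTable:
    """Rank labels per feature plus derived host / organelle flags.

    ``is_host`` is true when the genus (or any rank label) is in the
    configured host set; ``is_organelle`` when any rank label matches the
    configured organelle set case-insensitively.
    """

    ranks: pd.DataFrame  # index: feature_id; columns: TAXONOMY_RANKS
    host_set: frozenset[str] = DEFAULT_HOST_SET
    organelle_set: frozenset[str] = DEFAULT_ORGANELLE_SET

    def __post_init__(self) -> None:
        _check_axis_labels(self.ranks.index, "feature")
        missing = [c for c in TAXONOMY_RANKS if c not in self.ranks.columns]
        if missing:
            raise FormatError(f"taxonomy table missing rank columns {missing}")
        self.ranks = self.ranks[list(TAXONOMY_RANKS)].fillna("").astype(str)
        self.host_set = frozenset(self.host_set)
        organelles = {o.lower() for o in self.organelle_set}
        vals = self.ranks.to_numpy()
        self.is_host = pd.Series(
            np.isin(vals, list(self.host_set)).any(axis=1), index=self.ranks.index
        )
        lowered = np.char.lower(vals.astype(str))
        self.is_organelle = pd.Series(
            np.isin(lowered, list(organelles)).any(axis=1), index=self.ranks.index
        )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.ranks.index)

    def rank_of(self, feature_id: str, rank: str) -> str:
        return str(self.ranks.loc[feature_id, rank])


def read_taxonomy(
    path: str | Path,
    host_set: Iterable[str] = DEFAULT_HOST_SET,
    organelle_set: Iterable[str] = DEFAULT_ORGANELLE_SET,
) -> TaxonomyTable:
    frame = _read_table(path)
    frame.index.name = "feature_id"
    return TaxonomyTable(frame, frozenset(host_set), frozenset(organelle_set))


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(TAXONOMY_RANKS) + "\n")
        for fid, row in tax.ranks.iterrows():
            fh.write(str(fid) + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

METADATA_FIELDS = (
    "host_genus", "clade", "ecotype", "cruise", "isolation_method",
    "depth_m", "latitude", "longitude", "isolation_year",
)
_NUMERIC_METADATA = {"depth_m", "latitude", "longitude", "isolation_year"}


@dataclass
class SampleMetadata:
    """Per-culture isolation metadata; missing values are literal ``NA``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axis_labels(self.data.index, "sample")
        for col in METADATA_FIELDS:
            if col not in self.data.columns:
                self.data[col] = pd.NA
        for col in _NUMERIC_METADATA:
            self.data[col] = pd.to_numeric(self.data[col], errors="raise")
        depth = self.data["depth_m"]
        if (depth.dropna() < 0).any():
            bad = depth[depth < 0].index[0]
            raise FormatError(f"negative depth_m for sample {bad!r}")
        year = self.data["isolation_year"].dropna()
        if ((year < 1800) | (year > 2100)).any():
            bad = year[(year < 1800) | (year > 2100)].index[0]
            raise FormatError(f"implausible isolation_year for sample {bad!r}")

    def factor(self, name: str) -> pd.Series:
        """Return one metadata column with NA preserved (callers drop it)."""
        return self.data[name]


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = _read_table(path)
    frame = frame.replace("NA", pd.NA)
    frame.index.name = "sample_id"
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    frame = meta.data.fillna("NA")
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(frame.columns) + "\n")
        for sid, row in frame.iterrows():
            fh.write(str(sid) + "\t" + "\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# phylogenetic trees
# ---------------------------------------------------------------------------


@dataclass
class PhylogeneticTree:
    """A rooted, branch-lengthed tree whose tips are community features."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if len(tips) != len(set(tips)):
            dup = next(t for t in tips if tips.count(t) > 1)
            raise FormatError(f"duplicate tip label {dup!r}")
        n_missing = 0
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise FormatError(
                    f"negative branch length {node.length} at node {node.name!r}"
                )
        if self.tree.length is None:
            self.tree.length = 0.0
        if n_missing:
            logger.warning("%d branches lacked lengths; defaulted to 0", n_missing)

    @property
    def tip_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.tree.traverse(include_self=True))

    def scaled(self, factor: float) -> "PhylogeneticTree":
        clone = self.tree.copy()
        for node in clone.traverse(include_self=True):
            node.length = (node.length or 0.0) * factor
        return PhylogeneticTree(clone)


def read_tree(path: str | Path) -> PhylogeneticTree:
    path = Path(path)
    text = path.read_text()
    depth = 0
    for offset, char in enumerate(text):
        if char == "(":
            depth += 1
        elif char == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"{path}: unbalanced ')' at character {offset}")
    if depth != 0:
        raise FormatError(f"{path}: {depth} unclosed '(' at end of file")
    try:
        tree = skbio.TreeNode.read([text])
    except Exception as exc:
        raise FormatError(f"{path}: unparseable newick: {exc}") from exc
    return PhylogeneticTree(tree)


def write_tree(tree: PhylogeneticTree, path: str | Path) -> None:
    tree.tree.write(str(path))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase sequence mapping."""
    from Bio import SeqIO

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
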