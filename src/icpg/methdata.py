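"""Single-cell CpG coverage data: reading, binarization, depth filtering, splits.

Data model
----------
A :class:`CellMethylome` holds, per chromosome, position-sorted arrays of CpG
observations for one cell: 1-based position of the CpG cytosine, methylated
read count, total read count, and a ternary state (1 methylated,
0 unmethylated, -1 unknown).  A :class:`MethylationDataset` is an ordered
collection of cells; the order is fixed by the manifest and determines the
donor-block layout of downstream feature matrices.

Coordinates are 1-based positions of the cytosine on the forward strand;
strand collapsing of the CpG dyad is assumed done upstream, as scRRBS
pipelines emit merged calls.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

STATE_METH = 1
STATE_UNMETH = 0
STATE_UNKNOWN = -1

#: Chromosome holdout used throughout: disjoint train/test/validation
#: chromosome sets; autosomes 20-22 and the sex/mito chromosomes fall in
#: no set and are dropped by default.
DEFAULT_TRAIN_CHROMS = ("chr1", "chr3", "chr5", "chr7", "chr9", "chr11")
DEFAULT_TEST_CHROMS = ("chr2", "chr4", "chr6", "chr8", "chr10", "chr12")
DEFAULT_VALIDATION_CHROMS = (
    "chr13", "chr14", "chr15", "chr16", "chr17", "chr18", "chr19",
)


class CoverageParseError(ValueError):
    """A coverage file row failed to parse; carries the offending line number."""


def _norm_chrom(label: str) -> str:
    """Normalize a chromosome label to the 'chr*' form ('1' -> 'chr1')."""
    label = label.strip()
    return label if label.startswith("chr") else f"chr{label}"


@dataclass(frozen=True)
class SiteRecord:
    """One CpG observation in one cell."""

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int
    state: int = STATE_UNKNOWN

    def __post_init__(self) -> None:
        if self.meth_reads > self.total_reads:
            raise ValueError(
                f"meth_reads {self.meth_reads} > total_reads {self.total_reads} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.meth_reads < 0 or self.total_reads < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")
        if self.state not in (STATE_METH, STATE_UNMETH, STATE_UNKNOWN):
            raise ValueError(f"state must be -1, 0 or 1, got {self.state}")


@dataclass
class ChromSites:
    """Position-sorted site arrays for one chromosome of one cell."""

    pos: np.ndarray       # int64, strictly increasing
    meth: np.ndarray      # int64
    total: np.ndarray     # int64
    state: np.ndarray     # int8 in {-1, 0, 1}

    def __len__(self) -> int:
        return len(self.pos)


class CellMethylome:
    """Per-cell, per-chromosome sorted CpG site table.

    Positions within a chromosome are strictly increasing; a duplicated
    (chrom, pos) pair is rejected at construction.
    """

    def __init__(self, cell_id: str,
                 sites: Mapping[str, ChromSites] | None = None) -> None:
        self.cell_id = cell_id
        self.sites: dict[str, ChromSites] = dict(sites or {})
        for chrom, cs in self.sites.items():
            d = np.diff(cs.pos)
            if len(d) and d.min() <= 0:
                i = int(np.argmax(d <= 0))
                raise ValueError(
                    f"cell {cell_id}: duplicate or unsorted position "
                    f"{cs.pos[i + 1]} on {chrom}"
                )

    @classmethod
    def from_records(cls, cell_id: str,
                     records: Iterable[SiteRecord]) -> "CellMethylome":
        by_chrom: dict[str, list[SiteRecord]] = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(r)
        sites = {}
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: r.pos)
            for a, b in zip(rs, rs[1:]):
                if a.pos == b.pos:
                    raise ValueError(
                        f"cell {cell_id}: duplicate site ({chrom}, {a.pos})"
                    )
            sites[chrom] = ChromSites(
                pos=np.array([r.pos for r in rs], dtype=np.int64),
                meth=np.array([r.meth_reads for r in rs], dtype=np.int64),
                total=np.array([r.total_reads for r in rs], dtype=np.int64),
                state=np.array([r.state for r in rs], dtype=np.int8),
            )
        return cls(cell_id, sites)

    def chromosomes(self) -> list[str]:
        return sorted(self.sites)

    def n_sites(self) -> int:
        return sum(len(cs) for cs in self.sites.values())

    def iter_records(self) -> Iterator[SiteRecord]:
        for chrom in self.chromosomes():
            cs = self.sites[chrom]
            for i in range(len(cs)):
                yield SiteRecord(chrom, int(cs.pos[i]), int(cs.meth[i]),
                                 int(cs.total[i]), int(cs.state[i]))

    def to_frame(self) -> pd.DataFrame:
        rows = [(r.chrom, r.pos, r.meth_reads, r.total_reads, r.state)
                for r in self.iter_records()]
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "meth_reads", "total_reads", "state"]
        )


@dataclass
class MethylationDataset:
    """Ordered cells; order fixed by the manifest (drives feature layout)."""

    cells: list[CellMethylome] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate cell ids in dataset: {ids}")

    @property
    def w(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def cell(self, cell_id: str) -> CellMethylome:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(f"unknown cell id {cell_id!r}; have {self.cell_ids}")

    def chromosomes(self) -> list[str]:
        out: set[str] = set()
        for c in self.cells:
            out.update(c.sites)
        return sorted(out)

    def n_sites(self) -> int:
        return sum(c.n_sites() for c in self.cells)


@dataclass(frozen=True)
class ChromosomeSplit:
    """Disjoint train/test/validation chromosome sets (chromosome holdout)."""

    train: frozenset[str] = frozenset(DEFAULT_TRAIN_CHROMS)
    test: frozenset[str] = frozenset(DEFAULT_TEST_CHROMS)
    validation: frozenset[str] = frozenset(DEFAULT_VALIDATION_CHROMS)

    def __post_init__(self) -> None:
        sets = [frozenset(map(_norm_chrom, self.train)),
                frozenset(map(_norm_chrom, self.test)),
                frozenset(map(_norm_chrom, self.validation))]
        object.__setattr__(self, "train", sets[0])
        object.__setattr__(self, "test", sets[1])
        object.__setattr__(self, "validation", sets[2])
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("train/test/validation chromosome sets overlap")


def read_coverage_file(path: str | Path, dialect: str = "simple_tsv",
                       cell_id: str | None = None) -> CellMethylome:
    """Read one cell's CpG coverage table.

    Dialects
    --------
    ``simple_tsv``
        chrom, pos, methylated-read count, total-read count.
    ``bismark_cov``
        chrom, start, end, methylation %, count-methylated,
        count-unmethylated; ``pos`` is taken as start.  ``.gz`` accepted.

    States are initialized to unknown (-1); call
    :func:`binarize_and_filter` to assign them.  Duplicate (chrom, pos)
    rows are an error; unsorted input is accepted and sorted.
    """
    path = Path(path)
    if dialect not in ("simple_tsv", "bismark_cov"):
        raise ValueError(f"unknown dialect {dialect!r}")
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[SiteRecord] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "simple_tsv":
                    chrom, pos, meth, total = (
                        _norm_chrom(fields[0]), int(fields[1]),
                        int(fields[2]), int(fields[3]))
                else:
                    chrom = _norm_chrom(fields[0])
                    pos = int(fields[1])
                    meth = int(fields[4])
                    total = meth + int(fields[5])
                records.append(SiteRecord(chrom, pos, meth, total))
            except (IndexError, ValueError) as exc:
                raise CoverageParseError(
                    f"{path}:{lineno}: malformed {dialect} row: {line!r} ({exc})"
                ) from exc
    return CellMethylome.from_records(cell_id or path.stem, records)


def read_manifest(path: str | Path, dialect: str = "simple_tsv"
                  ) -> MethylationDataset:
    """Read a dataset manifest: TSV of (cell_id, coverage file path).

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    cells = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CoverageParseError(
                    f"{path}:{lineno}: manifest rows need 2 columns, "
                    f"got {len(parts)}")
            cell_id, fpath = parts
            f = Path(fpath)
            if not f.is_absolute():
                f = path.parent / f
            if not f.exists():
                raise FileNotFoundError(
                    f"{path}:{lineno}: coverage file not found: {f}")
            cells.append(read_coverage_file(f, dialect=dialect, cell_id=cell_id))
    return MethylationDataset(cells)


def binarize_and_filter(cell: CellMethylome, min_depth: int = 4,
                        meth_threshold: float = 0.5) -> CellMethylome:
    """Depth-filter and binarize a cell's sites.

    Sites with fewer than ``min_depth`` total reads are removed (the usual
    quality floor for scRRBS state calls is four reads); remaining sites get
    state 1 when the methylated-read fraction is >= ``meth_threshold``,
    else 0.  Idempotent: a second application changes nothing.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0 < meth_threshold <= 1:
        raise ValueError("meth_threshold must be in (0, 1]")
    out: dict[str, ChromSites] = {}
    for chrom, cs in cell.sites.items():
        keep = cs.total >= min_depth
        if not keep.any():
            continue
        total = cs.total[keep]
        meth = cs.meth[keep]
        state = (meth / total >= meth_threshold).astype(np.int8)
        out[chrom] = ChromSites(pos=cs.pos[keep].copy(), meth=meth.copy(),
                                total=total.copy(), state=state)
    return CellMethylome(cell.cell_id, out)


def _subset_cell(cell: CellMethylome, chroms: frozenset[str]) -> CellMethylome:
    sites = {c: ChromSites(cs.pos.copy(), cs.meth.copy(), cs.total.copy(),
                           cs.state.copy())
             for c, cs in cell.sites.items() if c in chroms}
    return CellMethylome(cell.cell_id, sites)


def split_by_chromosome(
    ds: MethylationDataset, split: ChromosomeSplit | None = None
) -> tuple[MethylationDataset, MethylationDataset, MethylationDataset]:
    """Partition a dataset into train/test/validation views by chromosome.

    Chromosomes belonging to none of the three sets are excluded entirely;
    cell order is preserved in every view.
    """
    split = split or ChromosomeSplit()
    views = []
    for chroms in (split.train, split.test, split.validation):
        views.append(MethylationDataset(
            [_subset_cell(c, chroms) for c in ds.cells]))
    return views[0], views[1], views[2]


def write_predictions(records: Sequence[tuple[str, str, int, float, int]],
                      path: str | Path) -> None:
    """Write predictions as a BED-like TSV.

    Columns: chrom, pos-1, pos, cell_id, probability, label — half-open
    0-based intervals, sorted by (cell, chrom, pos).
    """
    for cell_id, chrom, pos, prob, label in records:
        if not 0.0 <= prob <= 1.0:
            raise ValueError(
                f"probability {prob} out of [0, 1] at {cell_id} {chrom}:{pos}")
        if label not in (0, 1):
            raise ValueError(f"label {label} not in {{0, 1}}")
    ordered = sorted(records, key=lambda r: (r[0], r[1], r[2]))
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        fh.write("#chrom\tstart\tend\tcell_id\tprobability\tlabel\n")
        for cell_id, chrom, pos, prob, label in ordered:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{cell_id}\t"
                     f"{prob:g}\t{label}\n")
    tmp.replace(path)


def write_coverage_file(cell: CellMethylome, path: str | Path,
                        dialect: str = "simple_tsv") -> None:
    """Write one cell's sites back out (round-trips with read_coverage_file)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for r in cell.iter_records():
            if dialect == "simple_tsv":
                fh.write(f"{r.chrom}\t{r.pos}\t{r.meth_reads}\t{r.total_reads}\n")
            elif dialect == "bismark_cov":
                pct = 100.0 * r.meth_reads / r.total_reads if r.total_reads else 0.0
                fh.write(f"{r.chrom}\t{r.pos}\t{r.pos}\t{pct:g}\t"
                         f"{r.meth_reads}\t{r.total_reads - r.meth_reads}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    tmp.replace(path)
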