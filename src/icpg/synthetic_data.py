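"""Synthetic multi-cell CpG methylomes with island structure, cross-cell
concordance and coverage dropout.

The generator emulates the regime of single-cell reduced-representation
bisulphite sequencing: CpG positions cluster into dense islands separated
by sparse open sea; methylation state is regionally coherent (islands
mostly unmethylated, sea mostly methylated, giving an unmethylated-majority
class balance); cells agree with a per-site latent consensus with
probability rho; and each cell observes only a fraction q of sites, with
read depths floored at the usual 4-read state-calling threshold.

Two generators share one site scaffold:

* :func:`simulate_dataset` — full model: spatially correlated consensus,
  per-cell concordance rho, coverage dropout q.
* :func:`simulate_null` — same scaffold, but every cell/site state is an
  independent fair coin; no positional or cross-cell signal exists by
  construction.  Any model scoring above chance on this output is leaking.

Both are deterministic given ``SimulationParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methdata import CellMethylome, ChromSites, MethylationDataset


def _default_chroms() -> tuple[tuple[str, int], ...]:
    return (("chr1", 1_600_000), ("chr2", 1_600_000), ("chr3", 1_600_000))


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic methylome.

    Defaults give ~2000 CpGs per 1.6 Mb chromosome in alternating
    island/sea runs, 6 cells with concordance 0.95 and per-cell coverage
    0.30 — a desk-scale analogue of sparse scRRBS data.
    """

    w: int = 6                       # cells
    chroms: tuple[tuple[str, int], ...] = field(default_factory=_default_chroms)
    island_rate: float = 60.0        # mean islands per Mb
    island_size: float = 15.0        # mean CpGs per island
    gap_within: float = 80.0         # mean bp between island CpGs
    gap_between: float = 3000.0      # mean bp between sea CpGs
    p_meth_island: float = 0.25      # P(island latent state = methylated)
    p_meth_sea: float = 0.75         # P(sea latent state = methylated)
    flip_with_distance: float = 0.02  # per-kb deviation from regional state
    concordance: float = 0.95        # rho: P(cell state == consensus)
    coverage: float = 0.30           # q: P(cell observes a site)
    depth_mean: float = 10.0         # mean reads per observed site
    bisulphite_error: float = 0.05   # minority-read rate per observed site
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.concordance <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("concordance and coverage must be in [0, 1]")
        for name in ("island_rate", "island_size", "gap_within",
                     "gap_between", "depth_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.w < 1:
            raise ValueError("need at least one cell")


def _chrom_scaffold(rng: np.random.Generator, length: int,
                    p: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """CpG positions plus a region id per site (alternating island/sea runs).

    Region ids are even for islands, odd for sea, increasing along the
    chromosome; they anchor the regional latent-state process.
    """
    positions: list[int] = []
    region: list[int] = []
    # sea sites per cycle chosen so mean cycle span is 1e6 / island_rate
    cycle_span = 1e6 / p.island_rate
    n_sea_mean = max(1.0, (cycle_span - p.island_size * p.gap_within)
                     / p.gap_between)
    pos = 1
    rid = 0
    while pos < length:
        n_isl = 1 + rng.poisson(max(p.island_size - 1, 0.0))
        for _ in range(n_isl):
            pos += 1 + rng.geometric(1.0 / p.gap_within)
            if pos >= length:
                break
            positions.append(pos)
            region.append(rid)
        rid += 1
        n_sea = 1 + rng.poisson(max(n_sea_mean - 1, 0.0))
        for _ in range(n_sea):
            pos += 1 + rng.geometric(1.0 / p.gap_between)
            if pos >= length:
                break
            positions.append(pos)
            region.append(rid)
        rid += 1
    return (np.asarray(positions, dtype=np.int64),
            np.asarray(region, dtype=np.int64))


def _consensus_states(rng: np.random.Generator, positions: np.ndarray,
                      region: np.ndarray, p: SimulationParams) -> np.ndarray:
    """Per-site latent consensus: regional state, flipped with a
    probability growing with distance from the region anchor."""
    states = np.empty(len(positions), dtype=np.int8)
    for rid in np.unique(region):
        mask = region == rid
        is_island = rid % 2 == 0
        p_meth = p.p_meth_island if is_island else p.p_meth_sea
        regional = 1 if rng.random() < p_meth else 0
        pos_r = positions[mask]
        d_kb = (pos_r - pos_r[0]) / 1000.0
        p_flip = np.minimum(0.49, p.flip_with_distance * d_kb)
        flip = rng.random(len(pos_r)) < p_flip
        states[mask] = np.where(flip, 1 - regional, regional)
    return states


def _draw_reads(rng: np.random.Generator, states: np.ndarray,
                p: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Read counts per observed site: total = 4 + Poisson(depth_mean - 4)
    (keeps every site at or above the 4-read depth filter), methylated
    reads a clamped minority/majority consistent with the cell state."""
    n = len(states)
    total = 4 + rng.poisson(max(p.depth_mean - 4.0, 0.0), size=n)
    errors = rng.binomial(total, p.bisulphite_error)
    # clamp so the majority of reads always matches the state
    errors = np.minimum(errors, (total - 1) // 2)
    meth = np.where(states == 1, total - errors, errors)
    return meth.astype(np.int64), total.astype(np.int64)


def _build(params: SimulationParams, null: bool
           ) -> tuple[MethylationDataset, pd.DataFrame]:
    rng = np.random.default_rng(params.seed)
    cell_ids = [f"cell{i:02d}" for i in range(params.w)]
    truth_rows = []
    cells: dict[str, dict[str, ChromSites]] = {cid: {} for cid in cell_ids}
    for chrom, length in params.chroms:
        positions, region = _chrom_scaffold(rng, length, params)
        n = len(positions)
        if null:
            consensus = np.full(n, -1, dtype=np.int8)
            cell_states = rng.integers(0, 2, size=(params.w, n)).astype(np.int8)
        else:
            consensus = _consensus_states(rng, positions, region, params)
            agree = rng.random((params.w, n)) < params.concordance
            cell_states = np.where(agree, consensus, 1 - consensus
                                   ).astype(np.int8)
        observed = rng.random((params.w, n)) < params.coverage
        for ci, cid in enumerate(cell_ids):
            mask = observed[ci]
            if not mask.any():
                continue
            st = cell_states[ci, mask]
            meth, total = _draw_reads(rng, st, params)
            cells[cid][chrom] = ChromSites(
                pos=positions[mask].copy(), meth=meth, total=total,
                state=st.copy())
        truth = pd.DataFrame({"chrom": chrom, "pos": positions,
                              "region": region, "consensus": consensus})
        for ci, cid in enumerate(cell_ids):
            truth[f"state_{cid}"] = cell_states[ci]
            truth[f"observed_{cid}"] = observed[ci]
        truth_rows.append(truth)
    ds = MethylationDataset(
        [CellMethylome(cid, cells[cid]) for cid in cell_ids])
    return ds, pd.concat(truth_rows, ignore_index=True)


def simulate_dataset(params: SimulationParams
                     ) -> tuple[MethylationDataset, pd.DataFrame]:
    """Generate a spatially and cross-cell correlated multi-cell methylome.

    Returns the dataset (states already binarized; read counts consistent
    with each state) and a truth table with one row per scaffold site:
    chrom, pos, region id, latent consensus, and per-cell true state and
    observation flags.
    """
    return _build(params, null=False)


def simulate_null(params: SimulationParams
                  ) -> tuple[MethylationDataset, pd.DataFrame]:
    """Same site scaffold, but i.i.d. fair-coin states everywhere.

    The truth table's ``consensus`` column is -1: no consensus exists.
    """
    return _build(params, null=True)


def write_simulation(ds: MethylationDataset, truth: pd.DataFrame,
                     outdir: str | Path, dialect: str = "simple_tsv") -> Path:
    """Write per-cell coverage files, a manifest and the truth TSV."""
    from .methdata import write_coverage_file

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    ext = "cov" if dialect == "bismark_cov" else "tsv"
    with open(manifest, "w") as fh:
        for cell in ds.cells:
            fname = f"{cell.cell_id}.{ext}"
            write_coverage_file(cell, outdir / fname, dialect=dialect)
            fh.write(f"{cell.cell_id}\t{fname}\n")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return manifest
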