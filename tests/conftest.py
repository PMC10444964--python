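"""Shared fixtures: tiny hand-built methylomes and small simulations."""

from __future__ import annotations

import numpy as np
import pytest

from icpg.methdata import CellMethylome, MethylationDataset, SiteRecord
from icpg.synthetic_data import SimulationParams


def make_cell(cell_id: str, chrom_sites: dict[str, list[tuple[int, int]]]
              ) -> CellMethylome:
    """Cell from {chrom: [(pos, state), ...]}; read counts consistent
    with the state at depth 5."""
    records = []
    for chrom, sites in chrom_sites.items():
        for pos, state in sites:
            meth = 5 if state == 1 else 0
            records.append(SiteRecord(chrom, pos, meth, 5, state))
    return CellMethylome.from_records(cell_id, records)


@pytest.fixture
def five_site_cell() -> CellMethylome:
    """The canonical worked example: positions 10..100, states 1,0,1,1,0."""
    return make_cell("c0", {"chr1": [(10, 1), (25, 0), (40, 1),
                                     (70, 1), (100, 0)]})


@pytest.fixture
def small_params() -> SimulationParams:
    """Desk-scale simulation: 3 short chromosomes, ~250 CpGs each."""
    return SimulationParams(
        chroms=(("chr1", 200_000), ("chr2", 200_000), ("chr3", 200_000)),
        seed=11)


def random_dataset(rng: np.random.Generator, n_cells: int,
                   max_sites: int = 50,
                   chroms: tuple[str, ...] = ("chr1",)) -> MethylationDataset:
    """Random small dataset for oracle-equivalence scans."""
    cells = []
    for i in range(n_cells):
        chrom_sites = {}
        for chrom in chroms:
            n = int(rng.integers(0, max_sites + 1))
            pos = np.sort(rng.choice(np.arange(1, 2000), size=n,
                                     replace=False))
            states = rng.integers(0, 2, size=n)
            chrom_sites[chrom] = [(int(p), int(s))
                                  for p, s in zip(pos, states)]
        cells.append(make_cell(f"c{i}", chrom_sites))
    return MethylationDataset(cells)
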