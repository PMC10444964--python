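"""Positional CpG features: intra-cell skip-K neighbors and cross-cell F/D blocks.

The predictive signal exploited here is purely positional: methylation
states of CpG sites are spatially correlated within a cell and concordant
across cells at homologous positions.  For a target site (chrom, pos) in a
target cell the feature vector concatenates

* an **intra-cell block** (skip-K neighbors): for neighbor ranks
  j = 1..J on each side, the signed distance to the j-th nearest CpG
  site and that site's state — rank 1 is the immediate neighbor, rank 2
  skips one site, and so on.  The target's own state is never included.
  Default J=2 gives 4*J = 8 values.

* one **cross-cell block of 14 values per donor cell** (every cell in the
  dataset except the target, in manifest order):

  - ``match_flag`` — 1 if the donor has a CpG observation at exactly the
    target's position, else 0;
  - ``match_state`` — the donor's state at that position (-1 when no match);
  - ``F4`` — signed distance and state of the donor sites flanking the
    target position (the sites at ranks l-1 and l+1 around an exact match
    at index l, or the two sites bracketing the position when there is no
    match);
  - ``D8`` — four (gap length, state) pairs over the donor window
    l-2..l+2 around an exact match: consecutive inter-site gaps paired
    with the outer site's state (s_{l-2}, s_{l-1}, s_{l+1}, s_{l+2}).
    Defined only around an exact positional match; all-sentinel otherwise.

Missing neighbors and flanks are encoded as (sentinel distance, unknown
state -1); the sentinel is a large base-pair distance (default 1e6) so
tree ensembles can split on it without imputation.  Upstream distances are
negative, downstream positive; D gaps are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methdata import CellMethylome, ChromSites, MethylationDataset, STATE_UNKNOWN

DEFAULT_SENTINEL = 1_000_000.0
_EMPTY = ChromSites(pos=np.empty(0, dtype=np.int64),
                    meth=np.empty(0, dtype=np.int64),
                    total=np.empty(0, dtype=np.int64),
                    state=np.empty(0, dtype=np.int8))


@dataclass(frozen=True)
class NeighborContext:
    """Intra-cell skip-K neighbor features for one target site."""

    target: tuple[str, int]
    up_ranks: tuple[tuple[float, int], ...]    # (signed distance < 0, state)
    down_ranks: tuple[tuple[float, int], ...]  # (signed distance > 0, state)
    J: int

    def values(self) -> list[float]:
        out: list[float] = []
        for d, s in self.up_ranks:
            out.extend((d, s))
        for d, s in self.down_ranks:
            out.extend((d, s))
        return out


@dataclass(frozen=True)
class CrossCellBlock:
    """F/D features contributed by one donor cell for one target site."""

    donor_cell_id: str
    match_flag: int
    match_state: int
    F: tuple[float, ...]  # (left dist, left state, right dist, right state)
    D: tuple[float, ...]  # 4 x (gap, state), sentinel unless exact match

    def values(self) -> list[float]:
        return [self.match_flag, self.match_state, *self.F, *self.D]


def intra_cell_features(cell: CellMethylome, chrom: str, pos: int,
                        J: int = 2,
                        sentinel: float = DEFAULT_SENTINEL) -> NeighborContext:
    """Skip-K neighbor context of a site within its own cell.

    For each rank j = 1..J returns the j-th nearest upstream and downstream
    CpG site as (neighbor_pos - pos, state); absent neighbors are
    (-/+sentinel, -1).  The target must be a site of ``cell``.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    cs = cell.sites.get(chrom)
    if cs is None:
        raise KeyError(f"cell {cell.cell_id}: no sites on {chrom}")
    i = int(np.searchsorted(cs.pos, pos))
    if i >= len(cs.pos) or cs.pos[i] != pos:
        raise KeyError(f"cell {cell.cell_id}: {chrom}:{pos} is not a site")
    up, down = [], []
    for j in range(1, J + 1):
        k = i - j
        up.append((float(cs.pos[k] - pos), int(cs.state[k])) if k >= 0
                  else (-sentinel, STATE_UNKNOWN))
        k = i + j
        down.append((float(cs.pos[k] - pos), int(cs.state[k]))
                    if k < len(cs.pos) else (sentinel, STATE_UNKNOWN))
    return NeighborContext((chrom, pos), tuple(up), tuple(down), J)


def _donor_site(cs: ChromSites, idx: int,
                sentinel_dist: float) -> tuple[float, int, bool]:
    """(position-or-sentinel, state, in-range) for a donor index."""
    if 0 <= idx < len(cs.pos):
        return float(cs.pos[idx]), int(cs.state[idx]), True
    return sentinel_dist, STATE_UNKNOWN, False


def cross_cell_features(target_cell_id: str, chrom: str, pos: int,
                        donor: CellMethylome,
                        sentinel: float = DEFAULT_SENTINEL) -> CrossCellBlock:
    """F/D features of a target position against one donor cell.

    Exact positional match at donor index l: match_state is the donor's
    state there, F holds the l-1/l+1 flanks, D the four gaps and outer
    states over l-2..l+2.  No match: F holds the two bracketing sites,
    D is all-sentinel.  Flanks beyond the donor's site range are sentinel.
    """
    if donor.cell_id == target_cell_id:
        raise ValueError("donor must differ from the target cell")
    cs = donor.sites.get(chrom, _EMPTY)
    i = int(np.searchsorted(cs.pos, pos))
    matched = i < len(cs.pos) and cs.pos[i] == pos

    def fl(idx: int, sign: float) -> tuple[float, int]:
        p, s, ok = _donor_site(cs, idx, sentinel)
        return ((p - pos), s) if ok else (sign * sentinel, s)

    if matched:
        left_d, left_s = fl(i - 1, -1.0)
        right_d, right_s = fl(i + 1, +1.0)
        F = (left_d, left_s, right_d, right_s)
        D: list[float] = []
        # consecutive gaps over window i-2..i+2, paired with the outer state
        for lo, hi, state_idx in ((i - 2, i - 1, i - 2), (i - 1, i, i - 1),
                                  (i, i + 1, i + 1), (i + 1, i + 2, i + 2)):
            p_lo, _, ok_lo = _donor_site(cs, lo, sentinel)
            p_hi, _, ok_hi = _donor_site(cs, hi, sentinel)
            _, s, ok_s = _donor_site(cs, state_idx, sentinel)
            gap = (p_hi - p_lo) if (ok_lo and ok_hi) else sentinel
            D.extend((gap, s if ok_s else STATE_UNKNOWN))
        return CrossCellBlock(donor.cell_id, 1, int(cs.state[i]), F, tuple(D))

    # no exact match: bracketing sites l (below) and l+1 = i (above)
    left_d, left_s = fl(i - 1, -1.0)
    right_d, right_s = fl(i, +1.0)
    F = (left_d, left_s, right_d, right_s)
    D_sent = (sentinel, STATE_UNKNOWN) * 4
    return CrossCellBlock(donor.cell_id, 0, STATE_UNKNOWN, F,
                          tuple(float(v) for v in D_sent))


def feature_names(cell_ids: list[str], target_cell_id: str,
                  J: int = 2) -> list[str]:
    """Deterministic column names: intra block, then donor blocks in
    manifest order with the target cell skipped."""
    names = []
    for j in range(1, J + 1):
        names += [f"intra_up{j}_dist", f"intra_up{j}_state"]
    for j in range(1, J + 1):
        names += [f"intra_down{j}_dist", f"intra_down{j}_state"]
    for cid in cell_ids:
        if cid == target_cell_id:
            continue
        names += [f"{cid}_match_flag", f"{cid}_match_state",
                  f"{cid}_F_left_dist", f"{cid}_F_left_state",
                  f"{cid}_F_right_dist", f"{cid}_F_right_state"]
        for g in range(1, 5):
            names += [f"{cid}_D_gap{g}", f"{cid}_D_state{g}"]
    return names


def assemble_feature_matrix(
    ds: MethylationDataset, target_cell_id: str,
    chroms: list[str] | None = None, J: int = 2,
    sentinel: float = DEFAULT_SENTINEL,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Positional feature matrix for every site of the target cell.

    Returns ``(X, y, index)``: one row per target-cell site on the given
    chromosomes (default: all of the target's chromosomes), the aligned
    state labels, and a (chrom, pos) index frame.  Row length is
    4*J + 14*(w-1).  Deterministic for a fixed dataset.
    """
    target = ds.cell(target_cell_id)  # raises KeyError if unknown
    donors = [c for c in ds.cells if c.cell_id != target_cell_id]
    use_chroms = sorted(set(target.sites) if chroms is None
                        else set(chroms) & set(target.sites))
    cols = feature_names(ds.cell_ids, target_cell_id, J)
    rows, labels, idx = [], [], []
    for chrom in use_chroms:
        cs = target.sites[chrom]
        for pos, state in zip(cs.pos, cs.state):
            pos = int(pos)
            row = intra_cell_features(target, chrom, pos, J, sentinel).values()
            for donor in donors:
                row += cross_cell_features(target_cell_id, chrom, pos,
                                           donor, sentinel).values()
            rows.append(row)
            labels.append(int(state))
            idx.append((chrom, pos))
    X = pd.DataFrame(rows, columns=cols, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int8)
    index = pd.DataFrame(idx, columns=["chrom", "pos"])
    return X, y, index
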