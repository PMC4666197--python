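"""Unbiased (minV, minJ) parameter-space exploration.

Every pairwise combination of minimum V and minimum J alignment lengths
(8..26 by default, 361 pairs) is scored on a positive control (error-free
CDR3-centered reads with a known truth table) and a negative control
(TCR-free decoy reads).  Per cell the grid records how many truth CDR3s
were recovered and how many distinct bogus CDR3s were called on the
negative set; relative sensitivity divides recoveries by the grid maximum.

Because candidate selection inside the extractor does not depend on the
thresholds, a cell's call set is exactly the threshold-filtered call set of
the grid minimum; the grid is therefore computed from one extraction pass
per read set.  Recovered and bogus counts are non-increasing in both
thresholds by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .extractor import ExtractionParams, iter_read_calls
from .germline import GermlineReference
from .reads import SequencingRead

DEFAULT_RANGE = range(8, 27)


@dataclass
class GridResult:
    chain: str
    read_length: int
    v_values: np.ndarray  # shape (nv,)
    j_values: np.ndarray  # shape (nj,)
    n_recovered: np.ndarray  # shape (nv, nj)
    n_bogus: np.ndarray  # shape (nv, nj)
    n_positive: int

    @property
    def relative_sensitivity(self) -> np.ndarray:
        peak = self.n_recovered.max()
        if peak == 0:
            return np.zeros_like(self.n_recovered, dtype=float)
        return self.n_recovered / peak

    def to_frame(self) -> pd.DataFrame:
        rel = self.relative_sensitivity
        rows = [
            {
                "min_v": int(v), "min_j": int(j),
                "n_recovered": int(self.n_recovered[a, b]),
                "n_bogus": int(self.n_bogus[a, b]),
                "relative_sensitivity": float(rel[a, b]),
            }
            for a, v in enumerate(self.v_values)
            for b, j in enumerate(self.j_values)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class OptimalSelection:
    chain: str
    read_length: int
    acceptable_bogus_max: int
    min_v: int
    min_j: int
    n_recovered: int
    n_bogus: int
    relative_sensitivity: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _threshold_grid(
    pairs: Sequence[tuple[int, int]], v_values: np.ndarray, j_values: np.ndarray
) -> np.ndarray:
    """Boolean (nv, nj) grid: does any (v_len, j_len) pair survive the cell?"""
    ok = np.zeros((len(v_values), len(j_values)), dtype=bool)
    for v_len, j_len in pairs:
        ok |= (v_values <= v_len)[:, None] & (j_values <= j_len)[None, :]
    return ok


def grid_search(
    positive_reads: Sequence[SequencingRead],
    truth_cdr3s: Sequence[str],
    negative_reads: Sequence[SequencingRead],
    ref: GermlineReference,
    chain: str,
    read_length: int,
    v_range: Sequence[int] = DEFAULT_RANGE,
    j_range: Sequence[int] = DEFAULT_RANGE,
    params_base: ExtractionParams = ExtractionParams(),
    negative_calls: Optional[list[dict]] = None,
) -> GridResult:
    """Score every (minV, minJ) pair for one chain and read length.

    ``truth_cdr3s`` holds the truth CDR3 nucleotide sequence of each
    positive-control transcript (one entry per transcript); a recovery is
    an exact nucleotide match of that truth CDR3 in the cell's call set.
    ``negative_calls`` lets callers share the expensive negative-control
    pass across chains (it is the output of ``iter_read_calls`` on the
    negative reads).
    """
    v_values = np.asarray(sorted(v_range), dtype=int)
    j_values = np.asarray(sorted(j_range), dtype=int)
    if v_values.size == 0 or j_values.size == 0:
        raise ValueError("empty parameter range")
    base = ExtractionParams(
        min_v_align=int(v_values.min()), min_j_align=int(j_values.min()),
        max_mismatches=params_base.max_mismatches,
        both_strands=params_base.both_strands,
    )

    pos_calls = iter_read_calls(positive_reads, ref, base)
    if negative_calls is None:
        negative_calls = iter_read_calls(negative_reads, ref, base)

    # calls by CDR3 nt for this chain
    def _by_cdr3(call_dicts) -> dict[str, list[tuple[int, int]]]:
        by: dict[str, list[tuple[int, int]]] = {}
        for calls in call_dicts:
            call = calls.get(chain)
            if call is None:
                continue
            by.setdefault(call.cdr3_nt, []).append(
                (call.v_match_len, call.j_match_len)
            )
        return by

    pos_by = _by_cdr3(pos_calls)
    neg_by = _by_cdr3(negative_calls)

    n_recovered = np.zeros((v_values.size, j_values.size), dtype=int)
    grids: dict[str, np.ndarray] = {}
    for cdr3 in set(truth_cdr3s):
        pairs = pos_by.get(cdr3)
        if pairs:
            grids[cdr3] = _threshold_grid(pairs, v_values, j_values)
    for cdr3 in truth_cdr3s:
        if cdr3 in grids:
            n_recovered += grids[cdr3]

    n_bogus = np.zeros_like(n_recovered)
    for pairs in neg_by.values():
        n_bogus += _threshold_grid(pairs, v_values, j_values)

    return GridResult(
        chain=chain, read_length=read_length,
        v_values=v_values, j_values=j_values,
        n_recovered=n_recovered, n_bogus=n_bogus,
        n_positive=len(truth_cdr3s),
    )


def select_optimal(grid: GridResult, acceptable_bogus_max: int = 0) -> OptimalSelection:
    """Best parameter pair at an acceptable false-discovery level.

    Among cells with ``n_bogus <= acceptable_bogus_max``, recovery is
    maximized; ties are broken by minimizing minV + minJ, then minV, then
    minJ.  No acceptable cell is an error (relax the bound).
    """
    acceptable = np.argwhere(grid.n_bogus <= acceptable_bogus_max)
    if acceptable.size == 0:
        raise ValueError(
            "no parameter pair meets the acceptable bogus-call bound; "
            "consider relaxing acceptable_bogus_max"
        )
    best_key = None
    best_cell = None
    for a, b in acceptable:
        v, j = int(grid.v_values[a]), int(grid.j_values[b])
        key = (-int(grid.n_recovered[a, b]), v + j, v, j)
        if best_key is None or key < best_key:
            best_key = key
            best_cell = (a, b)
    a, b = best_cell
    return OptimalSelection(
        chain=grid.chain, read_length=grid.read_length,
        acceptable_bogus_max=acceptable_bogus_max,
        min_v=int(grid.v_values[a]), min_j=int(grid.j_values[b]),
        n_recovered=int(grid.n_recovered[a, b]),
        n_bogus=int(grid.n_bogus[a, b]),
        relative_sensitivity=float(grid.relative_sensitivity[a, b]),
    )
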