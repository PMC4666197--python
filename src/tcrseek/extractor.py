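"""Read-level CDR3 clonotype extraction.

The caller scans each (cleaned) read for a germline V suffix match covering
the conserved Cys anchor and a germline J prefix match covering the
[FW]GXG anchor, under configurable minimum alignment lengths, and
aggregates the anchored, in-frame anchor-to-anchor calls into a clonotype
table keyed by (chain, CDR3 nucleotide sequence, V, J).  Stop-containing
calls are retained but flagged; ``filter_clonotypes`` removes them together
with any frameshifted entries, and ``collapse_to_aa`` merges nucleotide
variants that encode the same amino-acid CDR3 (convergent recombination).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .align import RawCall, raw_calls
from .germline import GermlineReference
from .reads import SequencingRead
from .util import translate
from .vdj import _index_for

CLONOTYPE_COLUMNS = [
    "chain", "cdr3_nt", "cdr3_aa", "v_name", "j_name", "read_count", "has_stop"
]


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable extraction stringency.

    ``min_v_align``/``min_j_align`` are the minimum ungapped alignment
    lengths required of the V and J matches (defaults mirror the upstream
    caller's defaults of 12/12; truth annotation uses 20/20).
    ``max_mismatches`` is a per-alignment mismatch budget (0 for control
    experiments).  ``both_strands`` is on by default: bulk RNA-seq libraries
    of the era are unstranded.
    """

    min_v_align: int = 12
    min_j_align: int = 12
    max_mismatches: int = 0
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_v_align < 1 or self.min_j_align < 1:
            raise ValueError("minimum alignment lengths must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def seed_k(self) -> int:
        shortest = min(self.min_v_align, self.min_j_align)
        if self.max_mismatches == 0:
            return max(4, min(8, shortest))
        return max(4, min(8, shortest // (self.max_mismatches + 1)))


@dataclass
class ClonotypeTable:
    """Extracted clonotypes plus provenance (params and input description)."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CLONOTYPE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"clonotype table missing columns: {sorted(missing)}")

    @property
    def total_reads(self) -> int:
        return int(self.df.read_count.sum())

    def cdr3_nt_set(self, chain: Optional[str] = None) -> set[str]:
        df = self.df if chain is None else self.df[self.df.chain == chain]
        return set(df.cdr3_nt)

    def to_tsv(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        self.df.to_csv(path, sep="\t", index=False)
        if provenance_path is not None:
            Path(provenance_path).write_text(
                json.dumps(self.provenance, indent=2, sort_keys=True) + "\n"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClonotypeTable":
        df = pd.read_csv(path, sep="\t")
        if "has_stop" not in df.columns:
            df["has_stop"] = df.cdr3_aa.str.contains(r"\*", regex=True)
        return cls(df=df)


def clean_reads(reads: Iterable[SequencingRead]) -> list[SequencingRead]:
    """Keep reads longer than 40 nt whose bases are all standard (ACGTN)."""
    standard = set("ACGTN")
    return [
        r for r in reads if len(r.sequence) > 40 and not (set(r.sequence) - standard)
    ]


def subsample_reads(
    reads: Sequence[SequencingRead], n: int, rng: np.random.Generator
) -> list[SequencingRead]:
    """Uniform subsample without replacement; deterministic given the rng.

    Requesting more reads than are available is an "insufficient depth"
    error — mirroring the pre-normalization step that drops shallow samples
    rather than padding them.
    """
    if n > len(reads):
        raise ValueError(
            f"insufficient depth: requested {n} reads from {len(reads)}"
        )
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]


def iter_read_calls(
    reads: Iterable[SequencingRead],
    ref: GermlineReference,
    params: ExtractionParams,
) -> list[dict[str, RawCall]]:
    """Per-read threshold-free candidate calls (one dict per read).

    Thresholds from ``params`` are *not* applied here; this is the shared
    single pass behind both ``extract_cdr3`` and the parameter grid.
    """
    index = _index_for(ref, k=params.seed_k)
    return [
        raw_calls(
            r.sequence, index,
            max_mismatches=params.max_mismatches,
            both_strands=params.both_strands,
        )
        for r in reads
    ]


def calls_to_table(
    per_read_calls: Iterable[dict[str, RawCall]],
    params: ExtractionParams,
    n_reads: int,
    provenance: dict | None = None,
) -> ClonotypeTable:
    """Threshold raw calls and aggregate into a clonotype table."""
    counts: dict[tuple[str, str, str, str], int] = {}
    for calls in per_read_calls:
        for chain, call in calls.items():
            if call.v_match_len < params.min_v_align:
                continue
            if call.j_match_len < params.min_j_align:
                continue
            key = (chain, call.cdr3_nt, call.v_name, call.j_name)
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for (chain, cdr3_nt, v_name, j_name), count in counts.items():
        aa = translate(cdr3_nt) if len(cdr3_nt) % 3 == 0 else ""
        rows.append(
            {
                "chain": chain, "cdr3_nt": cdr3_nt, "cdr3_aa": aa,
                "v_name": v_name, "j_name": j_name, "read_count": count,
                "has_stop": "*" in aa,
            }
        )
    df = pd.DataFrame(rows, columns=CLONOTYPE_COLUMNS)
    df = df.sort_values(
        ["chain", "read_count", "cdr3_nt"], ascending=[True, False, True]
    ).reset_index(drop=True)
    prov = dict(provenance or {})
    prov.update(
        {
            "min_v_align": params.min_v_align, "min_j_align": params.min_j_align,
            "max_mismatches": params.max_mismatches,
            "both_strands": params.both_strands, "n_input_reads": n_reads,
        }
    )
    return ClonotypeTable(df=df, provenance=prov)


def extract_cdr3(
    reads: Sequence[SequencingRead],
    ref: GermlineReference,
    params: ExtractionParams = ExtractionParams(),
    provenance: dict | None = None,
) -> ClonotypeTable:
    """Run the caller over a read set and aggregate clonotypes."""
    per_read = iter_read_calls(reads, ref, params)
    return calls_to_table(per_read, params, n_reads=len(reads), provenance=provenance)


def filter_clonotypes(table: ClonotypeTable) -> ClonotypeTable:
    """Drop frameshifted (length not divisible by 3) and stop-containing calls."""
    df = table.df
    in_frame = df.cdr3_nt.str.len() % 3 == 0
    keep = in_frame & ~df.has_stop.astype(bool)
    return ClonotypeTable(
        df=df[keep].reset_index(drop=True),
        provenance={**table.provenance, "filtered": True},
    )


def collapse_to_aa(table: ClonotypeTable) -> pd.DataFrame:
    """Merge nucleotide variants per amino-acid CDR3.

    Returns a frame with one row per (chain, cdr3_aa): summed read counts
    and the number of distinct nucleotide variants that converged on the
    same amino-acid sequence.
    """
    df = table.df
    out = (
        df.groupby(["chain", "cdr3_aa"], as_index=False)
        .agg(read_count=("read_count", "sum"), n_nt_variants=("cdr3_nt", "nunique"))
        .sort_values(["chain", "read_count", "cdr3_aa"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    return out
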