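"""Germline V/(D)/J/C gene segment references with CDR3 anchor annotations.

A recombined TCR transcript is assembled from a variable (V), optional
diversity (D, beta chain only), joining (J) and constant (C) gene segment.
The CDR3 region is delimited by two conserved anchor codons: the cysteine
near the 3' end of the V segment and the phenylalanine/tryptophan of the
F/W-G-X-G motif near the 5' end of the J segment.  This module loads and
validates such references, and can synthesize realistic fixture references
so that the whole pipeline runs without any external download.

Coordinates are 0-based and intervals half-open throughout the package.
The CDR3 is defined inclusive of both anchor codons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .util import translate, read_fasta, write_fasta

CHAINS = ("alpha", "beta")
SEGMENT_TYPES = ("V", "D", "J", "C")

#: Anchor codon offset from the V 3' end (conserved Cys starts 15 nt before the end).
V_ANCHOR_FROM_END = 15
#: Default J anchor offsets per chain in fixture references.  The J segment
#: contributes ``anchor_offset + 3`` nt to an untrimmed CDR3; alpha J genes
#: contribute more sequence to the CDR3 than beta J genes do.
J_ANCHOR_OFFSET = {"alpha": 24, "beta": 15}

ANCHOR_TABLE_COLUMNS = ["name", "chain", "segment_type", "anchor_offset", "frame_offset"]


class GermlineValidationError(ValueError):
    """Raised when a reference violates a structural invariant."""


@dataclass(frozen=True)
class GeneSegment:
    """A single germline gene segment.

    ``anchor_offset`` is the 0-based position of the first base of the
    conserved anchor codon (Cys for V, Phe/Trp of the F/W-G-X-G motif for J;
    ``None`` for D and C).  ``frame_offset`` is the offset at which
    translation of a recombined transcript starts in frame.
    """

    name: str
    chain: str
    segment_type: str
    sequence: str
    anchor_offset: int | None = None
    frame_offset: int = 0

    def validate(self) -> None:
        if self.chain not in CHAINS:
            raise GermlineValidationError(f"{self.name}: unknown chain {self.chain!r}")
        if self.segment_type not in SEGMENT_TYPES:
            raise GermlineValidationError(
                f"{self.name}: unknown segment type {self.segment_type!r}"
            )
        if not self.sequence:
            raise GermlineValidationError(f"{self.name}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise GermlineValidationError(
                f"{self.name}: sequence contains non-ACGT characters"
            )
        if self.segment_type in ("V", "J"):
            if self.anchor_offset is None:
                raise GermlineValidationError(
                    f"{self.name}: {self.segment_type} segment requires an anchor_offset"
                )
            if not 0 <= self.anchor_offset <= len(self.sequence) - 3:
                raise GermlineValidationError(
                    f"{self.name}: anchor_offset {self.anchor_offset} outside sequence"
                )
        if self.segment_type == "V":
            codon = self.anchor_codon()
            if codon not in ("TGT", "TGC"):
                raise GermlineValidationError(
                    f"{self.name}: V anchor codon {codon} does not encode Cys"
                )
        if self.segment_type == "J":
            motif_nt = self.sequence[self.anchor_offset : self.anchor_offset + 12]
            if len(motif_nt) < 12:
                raise GermlineValidationError(
                    f"{self.name}: J segment too short for F/W-G-X-G motif at anchor"
                )
            aa = translate(motif_nt)
            if aa[0] not in "FW" or aa[1] != "G" or aa[3] != "G":
                raise GermlineValidationError(
                    f"{self.name}: motif {aa} at anchor does not match [FW]-G-X-G"
                )

    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]


@dataclass
class GermlineReference:
    """A validated collection of gene segments, indexed by (chain, type)."""

    segments: list[GeneSegment]
    provenance: str = ""
    _by_key: dict[tuple[str, str], list[GeneSegment]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self._by_key = {}
        for seg in self.segments:
            self._by_key.setdefault((seg.chain, seg.segment_type), []).append(seg)
        self.validate()

    def validate(self) -> None:
        for seg in self.segments:
            seg.validate()
        for (chain, seg_type), segs in self._by_key.items():
            names = [s.name for s in segs]
            if len(names) != len(set(names)):
                dup = sorted({n for n in names if names.count(n) > 1})
                raise GermlineValidationError(
                    f"duplicate segment names in ({chain}, {seg_type}): {dup}"
                )
        for chain in self.chains():
            for required in ("V", "J", "C"):
                if not self._by_key.get((chain, required)):
                    raise GermlineValidationError(
                        f"chain {chain}: no {required} segment present"
                    )
            if chain == "beta" and not self._by_key.get(("beta", "D")):
                raise GermlineValidationError("beta chain requires at least one D segment")

    def chains(self) -> list[str]:
        return sorted({seg.chain for seg in self.segments})

    def segments_for(self, chain: str, segment_type: str) -> list[GeneSegment]:
        return list(self._by_key.get((chain, segment_type), []))

    def get(self, chain: str, segment_type: str, name: str) -> GeneSegment:
        for seg in self._by_key.get((chain, segment_type), []):
            if seg.name == name:
                return seg
        raise KeyError(f"no segment ({chain}, {segment_type}, {name})")

    def min_length(self, segment_types: Iterable[str] = ("V", "J")) -> int:
        lengths = [len(s.sequence) for s in self.segments if s.segment_type in segment_types]
        return min(lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermlineReference):
            return NotImplemented
        return sorted(self.segments, key=lambda s: s.name) == sorted(
            other.segments, key=lambda s: s.name
        )

    def write(self, fasta_path: str | Path, anchors_path: str | Path) -> None:
        """Serialize to a segment FASTA plus the sidecar anchor TSV."""
        write_fasta(
            fasta_path, [(seg.name, seg.sequence) for seg in self.segments]
        )
        rows = []
        for seg in self.segments:
            rows.append(
                {
                    "name": seg.name,
                    "chain": seg.chain,
                    "segment_type": seg.segment_type,
                    "anchor_offset": "" if seg.anchor_offset is None else seg.anchor_offset,
                    "frame_offset": seg.frame_offset,
                }
            )
        pd.DataFrame(rows, columns=ANCHOR_TABLE_COLUMNS).to_csv(
            anchors_path, sep="\t", index=False
        )


def load_germline(fasta_path: str | Path, anchors_path: str | Path) -> GermlineReference:
    """Load a germline reference from FASTA + anchor annotation TSV.

    Every FASTA record must match exactly one anchor row, and vice versa.
    Anchor-codon violations (a V whose anchor codon is not Cys, a J without
    the [FW]-G-X-G motif) are hard errors naming the offending segment.
    """
    records = read_fasta(fasta_path)
    anchors = pd.read_csv(anchors_path, sep="\t", dtype={"name": str})
    missing = set(ANCHOR_TABLE_COLUMNS) - set(anchors.columns)
    if missing:
        raise GermlineValidationError(f"anchor table missing columns: {sorted(missing)}")
    by_name = {}
    for _, row in anchors.iterrows():
        if row["name"] in by_name:
            raise GermlineValidationError(f"duplicate anchor row for {row['name']}")
        by_name[row["name"]] = row
    segments = []
    for name, seq in records:
        if name not in by_name:
            raise GermlineValidationError(f"no anchor annotation for segment {name}")
        row = by_name.pop(name)
        raw_anchor = row["anchor_offset"]
        anchor = None if pd.isna(raw_anchor) or raw_anchor == "" else int(raw_anchor)
        segments.append(
            GeneSegment(
                name=name,
                chain=str(row["chain"]),
                segment_type=str(row["segment_type"]),
                sequence=seq.upper(),
                anchor_offset=anchor,
                frame_offset=int(row["frame_offset"]),
            )
        )
    if by_name:
        raise GermlineValidationError(
            f"anchor rows without FASTA records: {sorted(by_name)}"
        )
    return GermlineReference(segments=segments, provenance=f"loaded:{fasta_path}")


# ---------------------------------------------------------------------------
# Fixture generation

_STOPS = ("TAA", "TAG", "TGA")
_NT = "ACGT"


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons, none of which is a stop codon."""
    out = []
    while len(out) < n:
        codon = "".join(_NT[i] for i in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def _comparison_window(seg_type: str, seq: str, anchor: int | None) -> str:
    """The region used for the pairwise-distinguishability check (anchors and
    the J motif are excluded: they are conserved by design)."""
    if seg_type == "V":
        window = seq[-50:]
        # anchor codon sits inside the window; mask it out
        pos = len(seq) - 50
        a = anchor - pos if anchor is not None and anchor >= pos else None
        if a is not None:
            window = window[:a] + window[a + 3 :]
        return window
    if seg_type == "J" and anchor is not None:
        return seq[:anchor] + seq[anchor + 12 :]
    return seq


def generate_fixture_germline(
    n_v: int,
    n_d: int,
    n_j: int,
    chain: str,
    seed: int,
    n_c: int = 1,
) -> GermlineReference:
    """Synthesize a deterministic, download-free germline reference.

    Segment lengths and anchor placements mimic the human TCR loci at a
    coarse level: V segments of 270-320 nt with the conserved Cys codon
    15 nt from the 3' end, J segments of 45-60 nt carrying the [FW]-G-X-G
    motif (anchor offset 15 for beta, 24 for alpha, reflecting the longer
    CDR3 contribution of alpha J genes), D segments of 10-16 nt, and a
    300 nt C segment.  Coding regions are stop-free in the recombination
    frame so that productivity of a simulated transcript is decided by its
    junctions, not by the germline scaffold.  Segments are regenerated until
    every same-type pair is < 80 % identical outside the anchors.
    """
    if chain not in CHAINS:
        raise ValueError(f"unknown chain {chain!r}")
    if n_v < 1 or n_j < 1 or n_c < 1:
        raise ValueError("n_v, n_j and n_c must all be >= 1")
    if chain == "beta" and n_d < 1:
        raise ValueError("beta chain requires n_d >= 1")
    rng = np.random.default_rng(seed)
    prefix = {"alpha": "simTRA", "beta": "simTRB"}[chain]
    segments: list[GeneSegment] = []

    def _add_distinct(make, seg_type: str, count: int) -> None:
        existing = [
            s for s in segments if s.segment_type == seg_type
        ]
        for i in range(count):
            for _attempt in range(100):
                seg = make(i)
                window = _comparison_window(seg_type, seg.sequence, seg.anchor_offset)
                ok = all(
                    _identity(
                        window,
                        _comparison_window(seg_type, prev.sequence, prev.anchor_offset),
                    )
                    < 0.80
                    for prev in existing
                )
                if ok:
                    segments.append(seg)
                    existing.append(seg)
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not generate a distinguishable segment")

    def make_v(i: int) -> GeneSegment:
        frame_offset = int(rng.integers(0, 3))
        n_codons = int(rng.integers(90, 107))  # 270-318 nt coding
        body = _random_codons(rng, n_codons)
        lead = "".join(_NT[j] for j in rng.integers(0, 4, size=frame_offset))
        seq = lead + body
        anchor = len(seq) - V_ANCHOR_FROM_END
        anchor_codon = "TGT" if rng.integers(0, 2) == 0 else "TGC"
        seq = seq[:anchor] + anchor_codon + seq[anchor + 3 :]
        return GeneSegment(
            name=f"{prefix}V{i + 1:02d}", chain=chain, segment_type="V",
            sequence=seq, anchor_offset=anchor, frame_offset=frame_offset,
        )

    def make_j(i: int) -> GeneSegment:
        anchor = J_ANCHOR_OFFSET[chain]
        n_codons = int(rng.integers((anchor + 12) // 3 + 3, 21))  # up to 60 nt
        seq = _random_codons(rng, n_codons)
        fw = ["TTT", "TTC", "TGG"][int(rng.integers(0, 3))]
        x = _random_codons(rng, 1)
        g1 = "GG" + _NT[rng.integers(0, 4)]
        g2 = "GG" + _NT[rng.integers(0, 4)]
        motif = fw + g1 + x + g2
        seq = seq[:anchor] + motif + seq[anchor + 12 :]
        return GeneSegment(
            name=f"{prefix}J{i + 1:02d}", chain=chain, segment_type="J",
            sequence=seq, anchor_offset=anchor, frame_offset=anchor % 3,
        )

    def make_d(i: int) -> GeneSegment:
        length = int(rng.integers(10, 17))
        seq = "".join(_NT[j] for j in rng.integers(0, 4, size=length))
        return GeneSegment(
            name=f"{prefix}D{i + 1:02d}", chain=chain, segment_type="D", sequence=seq
        )

    def make_c(i: int) -> GeneSegment:
        seq = "".join(_NT[j] for j in rng.integers(0, 4, size=300))
        return GeneSegment(
            name=f"{prefix}C{i + 1:02d}", chain=chain, segment_type="C", sequence=seq
        )

    _add_distinct(make_v, "V", n_v)
    if chain == "beta" or n_d > 0:
        _add_distinct(make_d, "D", n_d)
    _add_distinct(make_j, "J", n_j)
    _add_distinct(make_c, "C", n_c)
    return GermlineReference(
        segments=segments, provenance=f"fixture:{chain}:seed={seed}"
    )


def merge_references(*refs: GermlineReference) -> GermlineReference:
    """Combine per-chain references into one (e.g. alpha + beta fixtures)."""
    segments = [seg for ref in refs for seg in ref.segments]
    provenance = "+".join(ref.provenance for ref in refs)
    return GermlineReference(segments=segments, provenance=provenance)
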