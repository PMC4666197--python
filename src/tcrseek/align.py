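"""Seed-and-extend ungapped matching of reads against germline V/J segments.

This is the engine behind both truth annotation of simulated transcripts and
the read-level CDR3 caller.  Matching is deliberately ungapped with a small
per-side mismatch budget (0 by default): the tunable extraction parameters
of interest are *minimum alignment lengths*, and control reads are
error-free, so indel handling would only blur the acceptance surface.

A V candidate is an ungapped match that fully covers the segment's Cys
anchor codon; a J candidate must cover the [FW]GXG anchor codon.  A CDR3
call requires one candidate of each on the same chain, with the V anchor
strictly before the J anchor in the read and the two anchors in the same
reading frame.  The CDR3 spans anchor-codon start to anchor-codon end and
includes both codons.

Candidate choice (longest anchor-covering match; ties by segment name, then
leftmost read position) is independent of the minimum-alignment thresholds,
which are applied *after* selection.  This makes call sets exactly nested as
thresholds rise, and lets a parameter grid be evaluated from a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .germline import GermlineReference
from .util import reverse_complement, translate


@dataclass(frozen=True)
class SegmentMatch:
    seg_name: str
    seg_type: str
    chain: str
    read_start: int
    read_end: int
    seg_start: int
    seg_end: int

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class RawCall:
    """A threshold-free CDR3 candidate for one read and one chain."""

    chain: str
    v_name: str
    j_name: str
    v_match_len: int
    j_match_len: int
    v_anchor_read: int
    j_anchor_read: int
    cdr3_nt: str
    strand: str  # "+" read as given, "-" call found on the reverse complement

    @property
    def cdr3_aa(self) -> str:
        return translate(self.cdr3_nt)

    @property
    def in_frame(self) -> bool:
        return len(self.cdr3_nt) % 3 == 0

    @property
    def has_stop(self) -> bool:
        return "*" in self.cdr3_aa

    @property
    def productive(self) -> bool:
        return self.in_frame and not self.has_stop


class SegmentIndex:
    """k-mer index over the V and J segments of a reference."""

    def __init__(self, ref: GermlineReference, k: int = 8):
        self.ref = ref
        self.k = k
        self.entries: list[tuple[str, str, str, str, int]] = []
        # (chain, seg_type, name, sequence, anchor_offset)
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        self.anchors: dict[tuple[str, str, str], int] = {}
        for chain in ref.chains():
            for seg_type in ("V", "J"):
                for seg in ref.segments_for(chain, seg_type):
                    si = len(self.entries)
                    self.entries.append(
                        (chain, seg_type, seg.name, seg.sequence, seg.anchor_offset)
                    )
                    self.anchors[(chain, seg_type, seg.name)] = seg.anchor_offset
                    seq = seg.sequence
                    for p in range(len(seq) - k + 1):
                        self.kmers.setdefault(seq[p : p + k], []).append((si, p))

    def segment_matches(
        self, read: str, max_mismatches: int = 0
    ) -> list[SegmentMatch]:
        """All maximal ungapped matches of read vs indexed segments.

        Seeds are exact k-mers; each is extended maximally in both
        directions, first exactly and then (if a budget is given) greedily
        through isolated mismatches.  N bases never match.
        """
        k = self.k
        kmers = self.kmers
        out: list[SegmentMatch] = []
        seen: dict[tuple[int, int], int] = {}  # (si, diag) -> read_end reached
        n = len(read)
        for i in range(n - k + 1):
            hits = kmers.get(read[i : i + k])
            if not hits:
                continue
            for si, p in hits:
                diag = i - p
                if seen.get((si, diag), -1) > i:
                    continue
                chain, seg_type, name, seq, anchor = self.entries[si]
                # exact extension
                rs, ss = i, p
                while rs > 0 and ss > 0 and read[rs - 1] == seq[ss - 1]:
                    rs -= 1
                    ss -= 1
                re_, se = i + k, p + k
                m = len(seq)
                while re_ < n and se < m and read[re_] == seq[se]:
                    re_ += 1
                    se += 1
                budget = max_mismatches
                while budget > 0:
                    # try to hop one mismatch on the right, then the left
                    gained = False
                    if re_ < n - 1 and se < m - 1 and read[re_ + 1] == seq[se + 1]:
                        re_ += 1
                        se += 1
                        while re_ < n and se < m and read[re_] == seq[se]:
                            re_ += 1
                            se += 1
                        budget -= 1
                        gained = True
                    elif rs > 1 and ss > 1 and read[rs - 2] == seq[ss - 2]:
                        rs -= 1
                        ss -= 1
                        while rs > 0 and ss > 0 and read[rs - 1] == seq[ss - 1]:
                            rs -= 1
                            ss -= 1
                        budget -= 1
                        gained = True
                    if not gained:
                        break
                seen[(si, diag)] = re_
                out.append(
                    SegmentMatch(
                        seg_name=name, seg_type=seg_type, chain=chain,
                        read_start=rs, read_end=re_, seg_start=ss, seg_end=se,
                    )
                )
        return out


def _best_candidate(
    matches: list[SegmentMatch],
    index: SegmentIndex,
    chain: str,
    seg_type: str,
) -> Optional[tuple[SegmentMatch, int]]:
    """Longest anchor-covering match; returns (match, anchor_pos_in_read)."""
    best: Optional[tuple[SegmentMatch, int]] = None
    for m in matches:
        if m.chain != chain or m.seg_type != seg_type:
            continue
        anchor = index.anchors[(chain, seg_type, m.seg_name)]
        if not (m.seg_start <= anchor and m.seg_end >= anchor + 3):
            continue
        anchor_read = m.read_start + (anchor - m.seg_start)
        if best is None:
            best = (m, anchor_read)
            continue
        b, _ = best
        if (-m.length, m.seg_name, m.read_start) < (-b.length, b.seg_name, b.read_start):
            best = (m, anchor_read)
    return best


def _call_strand(read: str, index: SegmentIndex, chain: str, max_mm: int, strand: str
                 ) -> Optional[RawCall]:
    matches = index.segment_matches(read, max_mm)
    v = _best_candidate(matches, index, chain, "V")
    j = _best_candidate(matches, index, chain, "J")
    if v is None or j is None:
        return None
    (vm, v_anchor), (jm, j_anchor) = v, j
    if not v_anchor < j_anchor:
        return None
    if (j_anchor - v_anchor) % 3 != 0:
        return None
    if j_anchor + 3 > len(read):
        return None
    return RawCall(
        chain=chain, v_name=vm.seg_name, j_name=jm.seg_name,
        v_match_len=vm.length, j_match_len=jm.length,
        v_anchor_read=v_anchor, j_anchor_read=j_anchor,
        cdr3_nt=read[v_anchor : j_anchor + 3], strand=strand,
    )


def raw_calls(
    read: str,
    index: SegmentIndex,
    max_mismatches: int = 0,
    both_strands: bool = True,
    chains: tuple[str, ...] | None = None,
) -> dict[str, RawCall]:
    """Best threshold-free CDR3 candidate per chain for one read.

    With ``both_strands`` the read and its reverse complement are both
    evaluated and, per chain, the orientation with the larger total match
    length wins (ties: lexicographically smaller CDR3, then forward).  The
    selection does not depend on minimum-alignment thresholds, so the caller
    is strand-symmetric and threshold-monotone.
    """
    chains = chains or tuple(index.ref.chains())
    calls: dict[str, RawCall] = {}
    for chain in chains:
        fwd = _call_strand(read, index, chain, max_mismatches, "+")
        rev = None
        if both_strands:
            rev = _call_strand(
                reverse_complement(read), index, chain, max_mismatches, "-"
            )
        pick = None
        if fwd and rev:
            key_f = (-(fwd.v_match_len + fwd.j_match_len), fwd.cdr3_nt, 0)
            key_r = (-(rev.v_match_len + rev.j_match_len), rev.cdr3_nt, 1)
            pick = fwd if key_f <= key_r else rev
        else:
            pick = fwd or rev
        if pick is not None:
            calls[chain] = pick
    return calls
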