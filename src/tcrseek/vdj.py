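"""In silico V(D)J recombination of TCR alpha and beta transcripts.

Segments are chosen uniformly at random, trimmed and joined with
non-templated insertions drawn from a :class:`~tcrseek.junctions.JunctionModel`,
and the resulting full-length transcript (V + junction + J + C) is annotated
with its truth CDR3 at stringent alignment settings (minimum V and J
alignment length 20).  ``simulate_repertoire`` keeps only productive
transcripts: in frame from the V start through the C segment start, with no
stop codon, and with an annotatable Cys...Phe/Trp CDR3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .align import RawCall, SegmentIndex, raw_calls
from .germline import GermlineReference, GeneSegment
from .junctions import JunctionEvent, JunctionModel, sample_junction
from .util import translate, write_fasta

#: Stringent alignment settings used for truth annotation, matching the
#: strictest setting explored by the extraction grid.
TRUTH_MIN_V = 20
TRUTH_MIN_J = 20


@dataclass(frozen=True)
class CDR3Annotation:
    cdr3_nt_interval: tuple[int, int]
    cdr3_nt: str
    cdr3_aa: str
    v_name: str
    j_name: str
    v_match_len: int
    j_match_len: int

    @property
    def in_frame(self) -> bool:
        return len(self.cdr3_nt) % 3 == 0

    @property
    def has_stop(self) -> bool:
        return "*" in self.cdr3_aa


@dataclass
class RecombinedTranscript:
    """A simulated full-length TCR transcript with its junction record."""

    name: str
    chain: str
    v_name: str
    j_name: str
    c_name: str
    sequence: str
    junction: JunctionEvent
    d_name: Optional[str] = None
    cdr3_nt_interval: Optional[tuple[int, int]] = None
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    productive: bool = False


def assemble_sequence(
    v: GeneSegment,
    d: Optional[GeneSegment],
    j: GeneSegment,
    c: GeneSegment,
    event: JunctionEvent,
) -> str:
    """Deterministically rebuild the transcript from segments + junction."""
    v_part = v.sequence[: len(v.sequence) - event.del_v3]
    j_part = j.sequence[event.del_j5 :]
    if event.chain == "beta":
        if d is None:
            raise ValueError("beta assembly requires a D segment")
        d_part = d.sequence[event.del_d5 : len(d.sequence) - event.del_d3]
        return v_part + event.ins_vd + d_part + event.ins_dj + j_part + c.sequence
    return v_part + event.ins_vj + j_part + c.sequence


def recombine(
    ref: GermlineReference,
    chain: str,
    model: JunctionModel,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> RecombinedTranscript:
    """One random recombination.  The productive flag is left unset."""
    model.validate_against(ref)

    def _pick(seg_type: str) -> GeneSegment:
        segs = ref.segments_for(chain, seg_type)
        if not segs:
            raise ValueError(f"reference has no {seg_type} segments for chain {chain}")
        return segs[int(rng.integers(0, len(segs)))]

    v, j, c = _pick("V"), _pick("J"), _pick("C")
    d = _pick("D") if chain == "beta" else None
    for _ in range(max_retries):
        event = sample_junction(model, chain, rng)
        if event.del_v3 >= len(v.sequence) or event.del_j5 >= len(j.sequence):
            continue
        if chain == "beta" and event.del_d5 + event.del_d3 > len(d.sequence):
            continue
        seq = assemble_sequence(v, d, j, c, event)
        return RecombinedTranscript(
            name="", chain=chain, v_name=v.name,
            d_name=d.name if d else None, j_name=j.name, c_name=c.name,
            sequence=seq, junction=event,
        )
    raise RuntimeError(
        f"no feasible junction event for ({v.name}, {j.name}) after {max_retries} tries"
    )


def annotate_cdr3(
    sequence: str,
    ref: GermlineReference,
    min_v_align: int = TRUTH_MIN_V,
    min_j_align: int = TRUTH_MIN_J,
    max_mismatches: int = 0,
    chain: Optional[str] = None,
) -> Optional[CDR3Annotation]:
    """Locate the CDR3 of a full-length transcript, or return None.

    The best anchor-covering V and J matches are found with the same engine
    as the read-level extractor; the annotation is accepted only if both
    match lengths reach the requested minima.  Absence is a valid outcome.
    """
    if min_v_align < 1 or min_j_align < 1:
        raise ValueError("minimum alignment lengths must be >= 1")
    index = _index_for(ref, k=min(8, min_v_align, min_j_align))
    chains = (chain,) if chain else None
    calls = raw_calls(
        sequence, index, max_mismatches=max_mismatches,
        both_strands=False, chains=chains,
    )
    best: Optional[RawCall] = None
    for call in calls.values():
        if call.v_match_len >= min_v_align and call.j_match_len >= min_j_align:
            if best is None or (
                call.v_match_len + call.j_match_len
                > best.v_match_len + best.j_match_len
            ):
                best = call
    if best is None:
        return None
    return CDR3Annotation(
        cdr3_nt_interval=(best.v_anchor_read, best.j_anchor_read + 3),
        cdr3_nt=best.cdr3_nt, cdr3_aa=best.cdr3_aa,
        v_name=best.v_name, j_name=best.j_name,
        v_match_len=best.v_match_len, j_match_len=best.j_match_len,
    )


def _index_for(ref: GermlineReference, k: int = 8) -> SegmentIndex:
    cache = getattr(ref, "_segment_index_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(ref, "_segment_index_cache", cache)
    if k not in cache:
        cache[k] = SegmentIndex(ref, k=k)
    return cache[k]


def is_productive(transcript: RecombinedTranscript, ref: GermlineReference) -> bool:
    """In frame and stop-free from the V frame offset through the C start."""
    v = ref.get(transcript.chain, "V", transcript.v_name)
    c = ref.get(transcript.chain, "C", transcript.c_name)
    c_start = len(transcript.sequence) - len(c.sequence)
    orf = transcript.sequence[v.frame_offset : c_start]
    orf = orf[: len(orf) - len(orf) % 3]
    if "*" in translate(orf):
        return False
    ann = transcript.cdr3_nt
    if ann is not None and len(ann) % 3 != 0:
        return False
    return True


def _constructed_cdr3_interval(
    t: RecombinedTranscript, ref: GermlineReference
) -> Optional[tuple[int, int]]:
    """CDR3 interval implied by the junction record alone (no alignment)."""
    v = ref.get(t.chain, "V", t.v_name)
    j = ref.get(t.chain, "J", t.j_name)
    e = t.junction
    if e.del_j5 > j.anchor_offset or e.del_v3 > len(v.sequence) - (v.anchor_offset + 3):
        return None  # an anchor codon was chewed away
    start = v.anchor_offset
    v_part = len(v.sequence) - e.del_v3
    if t.chain == "beta":
        d = ref.get(t.chain, "D", t.d_name)
        mid = len(e.ins_vd) + (len(d.sequence) - e.del_d5 - e.del_d3) + len(e.ins_dj)
    else:
        mid = len(e.ins_vj)
    end = v_part + mid + (j.anchor_offset - e.del_j5) + 3
    return start, end


def simulate_repertoire(
    ref: GermlineReference,
    chain: str,
    n_target: int,
    model: JunctionModel,
    rng: np.random.Generator,
    min_acceptance: float = 0.01,
    trial_window: int = 2000,
) -> list[RecombinedTranscript]:
    """Rejection-sample ``n_target`` productive, truth-annotated transcripts.

    Out-of-frame products and products containing stop codons are rejected,
    as are transcripts whose CDR3 cannot be annotated at the stringent
    20/20 truth settings.  If the acceptance rate over an initial trial
    window falls below ``min_acceptance`` the reference or junction model is
    presumed broken and an error is raised.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    out: list[RecombinedTranscript] = []
    attempts = 0
    max_attempts = 10_000 * n_target
    while len(out) < n_target:
        if attempts >= max_attempts:
            raise RuntimeError("rejection-sampling attempt bound exceeded")
        if attempts == trial_window and len(out) / attempts < min_acceptance:
            raise RuntimeError(
                f"acceptance rate {len(out) / attempts:.4f} below {min_acceptance}: "
                "reference or junction model looks broken"
            )
        attempts += 1
        t = recombine(ref, chain, model, rng)
        # cheap junction-arithmetic precheck before paying for alignment
        interval = _constructed_cdr3_interval(t, ref)
        if interval is None or (interval[1] - interval[0]) % 3 != 0:
            continue
        if not is_productive(t, ref):
            continue
        ann = annotate_cdr3(t.sequence, ref, TRUTH_MIN_V, TRUTH_MIN_J, chain=chain)
        if ann is None or not ann.in_frame or ann.has_stop:
            continue
        if ann.cdr3_aa[0] != "C" or ann.cdr3_aa[-1] not in "FW":
            continue
        t.cdr3_nt_interval = ann.cdr3_nt_interval
        t.cdr3_nt = ann.cdr3_nt
        t.cdr3_aa = ann.cdr3_aa
        t.productive = True
        t.name = f"{chain}_{len(out):06d}"
        out.append(t)
    return out


def write_repertoire(
    transcripts: list[RecombinedTranscript],
    fasta_path: str | Path,
    truth_path: str | Path,
) -> None:
    """FASTA of transcript sequences + TSV truth table (junction and CDR3)."""
    write_fasta(fasta_path, [(t.name, t.sequence) for t in transcripts])
    rows = []
    for t in transcripts:
        e = t.junction
        rows.append(
            {
                "name": t.name, "chain": t.chain, "v": t.v_name,
                "d": t.d_name or "", "j": t.j_name, "c": t.c_name,
                "cdr3_start": t.cdr3_nt_interval[0] if t.cdr3_nt_interval else "",
                "cdr3_end": t.cdr3_nt_interval[1] if t.cdr3_nt_interval else "",
                "cdr3_nt": t.cdr3_nt or "", "cdr3_aa": t.cdr3_aa or "",
                "del_v3": e.del_v3, "del_d5": e.del_d5 if e.del_d5 is not None else "",
                "del_d3": e.del_d3 if e.del_d3 is not None else "", "del_j5": e.del_j5,
                "ins_vd": e.ins_vd or "", "ins_dj": e.ins_dj or "",
                "ins_vj": e.ins_vj or "",
            }
        )
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
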