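"""Control and benchmark read sets.

Three kinds of read sets drive benchmarking of the CDR3 extractor:

* **Positive controls** — one error-free read per simulated transcript with
  the CDR3 midpoint at the read midpoint.
* **Decoys** — a synthetic TCR-free negative control replacing pooled
  TCR-negative cell-line libraries.  Three modes: ``germline`` (windows of
  unrecombined segments), ``shuffled`` (dinucleotide-shuffled segments) and
  ``chimeric`` (near-TCR reads carrying short, low-similarity V-like and
  J-like fragments — the adversarial TCR-like non-TCR sequence that causes
  spurious calls at low alignment stringency).  No decoy read contains a
  productive anchor-to-anchor CDR3, and this is verified per read.
* **Expression-weighted RNA-seq** — reads drawn from a transcript pool
  (TCR + background) with log-normal expression, yielding datasets with a
  known per-transcript abundance table in TPM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import raw_calls
from .germline import GermlineReference
from .vdj import RecombinedTranscript, _index_for

_NT = "ACGT"

#: Chimeric decoys embed V-like / J-like fragments of these lengths (nt).
#: They bracket the extractor's default minimum alignment length of 12,
#: mimicking short, low-similarity spurious hits to TCR-like sequence.
CHIMERA_FRAGMENT_RANGE = (8, 14)


@dataclass
class SequencingRead:
    read_id: str
    sequence: str
    source_transcript: Optional[str] = None
    flagged_short: bool = False


@dataclass
class SimulatedDataset:
    reads: list[SequencingRead]
    read_length: int
    depth: int
    abundance_table: pd.DataFrame  # columns: transcript_id, tpm, is_tcr


# ---------------------------------------------------------------------------
# positive controls


def centered_reads(
    transcripts: Sequence[RecombinedTranscript], read_length: int
) -> list[SequencingRead]:
    """One error-free read per transcript, centered on the CDR3 midpoint.

    The CDR3 midpoint is placed at the read midpoint (both midpoints taken
    with floor).  Windows that would run past a transcript boundary are
    shifted inward to keep the full read length; transcripts shorter than
    the read become a single flagged whole-transcript read.
    """
    if read_length < 25:
        raise ValueError("read_length must be >= 25")
    out = []
    for t in transcripts:
        if t.cdr3_nt_interval is None:
            raise ValueError(f"{t.name}: transcript lacks a truth CDR3 interval")
        s, e = t.cdr3_nt_interval
        if len(t.sequence) <= read_length:
            out.append(
                SequencingRead(
                    read_id=f"{t.name}_r", sequence=t.sequence,
                    source_transcript=t.name, flagged_short=True,
                )
            )
            continue
        mid = (s + e) // 2
        start = mid - read_length // 2
        start = max(0, min(start, len(t.sequence) - read_length))
        out.append(
            SequencingRead(
                read_id=f"{t.name}_r",
                sequence=t.sequence[start : start + read_length],
                source_transcript=t.name,
            )
        )
    return out


def truncate_reads(
    reads: Sequence[SequencingRead], target_length: int
) -> list[SequencingRead]:
    """Keep the first ``target_length`` bases; shorter reads pass unchanged."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    return [
        SequencingRead(
            read_id=r.read_id, sequence=r.sequence[:target_length],
            source_transcript=r.source_transcript, flagged_short=r.flagged_short,
        )
        for r in reads
    ]


# ---------------------------------------------------------------------------
# decoys


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Eulerian-walk style)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])
    out = [seq[0]]
    # follow edges; fall back to a plain shuffle if the walk dead-ends early
    try:
        for _ in range(len(seq) - 1):
            out.append(edges[out[-1]].pop())
    except (KeyError, IndexError):
        chars = list(seq)
        rng.shuffle(chars)
        return "".join(chars)
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=n))


def _chimeric_read(
    ref: GermlineReference, read_length: int, rng: np.random.Generator
) -> str:
    """One chimeric decoy read.

    Half the reads are *bogus-call* chimeras: a short V fragment covering
    the Cys anchor, then (in the V frame) a planted stop codon, then a short
    J fragment covering its anchor, with anchors in frame.  These trigger
    nonproductive CDR3 calls whenever both fragments reach the minimum
    alignment lengths, so an optimizer must raise stringency to silence
    them.  The other half are *geometry-failing* chimeras (J-like fragment
    before V-like fragment) that align to both segment families but can
    never satisfy anchor geometry.  Fragment boundaries are mismatch-guarded
    so the alignment length equals the planted fragment length.
    """
    lo, hi = CHIMERA_FRAGMENT_RANGE
    chain = ref.chains()[int(rng.integers(0, len(ref.chains())))]
    vs = ref.segments_for(chain, "V")
    js = ref.segments_for(chain, "J")
    v = vs[int(rng.integers(0, len(vs)))]
    j = js[int(rng.integers(0, len(js)))]
    v_take = int(rng.integers(lo, hi + 1))
    j_take = int(rng.integers(lo, hi + 1))
    va = v.anchor_offset
    v_frag = v.sequence[va + 3 - v_take : va + 3]  # ends exactly at anchor end
    pre = int(rng.integers(0, j_take - 2))  # J positions before the anchor
    ja = j.anchor_offset
    j_start = ja - pre
    if j_start < 0:
        pre = ja
        j_start = 0
    j_frag = j.sequence[j_start : j_start + j_take]

    def _guard(not_equal_to: str) -> str:
        choices = [b for b in _NT if b != not_equal_to]
        return choices[int(rng.integers(0, len(choices)))]

    v_left = v.sequence[va + 2 - v_take] if va + 3 - v_take > 0 else ""
    v_right = v.sequence[va + 3] if va + 3 < len(v.sequence) else ""
    j_left = j.sequence[j_start - 1] if j_start > 0 else ""
    j_right = j.sequence[j_start + j_take] if j_start + j_take < len(j.sequence) else ""
    if rng.integers(0, 2) == 0:
        # Bogus-call subtype: V-like ... stop ... J-like with anchors in
        # frame.  Layout after the V fragment: 3 nt pad (first base guarded
        # against extending the V match), an in-frame stop codon, then a
        # gap chosen so the J anchor lands in the V anchor's frame, with its
        # last base guarded against extending the J match leftward.
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        pad = _guard(v_right) + _random_seq(rng, 2)
        g2 = int(rng.integers(1, 3)) * 3 + (3 - pre % 3) % 3  # >= 3
        gap_rest = _random_seq(rng, g2 - 1) + _guard(j_left)
        core = (
            _guard(v_left) + v_frag + pad + stop + gap_rest + j_frag + _guard(j_right)
        )
    else:
        # geometry-failing subtype: J-like fragment first, then V-like
        core = (
            _guard(j_left)
            + j_frag
            + _guard(j_right)
            + _random_seq(rng, int(rng.integers(2, 8)))
            + _guard(v_left)
            + v_frag
            + _guard(v_right)
        )
    if len(core) >= read_length:
        return core[:read_length]
    n_pad = read_length - len(core)
    n_left = int(rng.integers(0, n_pad + 1))
    return _random_seq(rng, n_left) + core + _random_seq(rng, n_pad - n_left)


def decoy_reads(
    ref: GermlineReference,
    n: int,
    read_length: int,
    rng: np.random.Generator,
    mode: str = "germline",
    max_regenerate: int = 50,
) -> list[SequencingRead]:
    """TCR-free decoy reads; construction verified per read.

    ``germline`` and ``shuffled`` reads must yield *no* CDR3 call at all at
    minimum stringency 8/8; ``chimeric`` reads may yield nonproductive
    (stop-containing) calls — that is their purpose — but never productive
    ones.  A read failing verification is regenerated (bounded).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("germline", "shuffled", "chimeric"):
        raise ValueError(f"unknown decoy mode {mode!r}")
    index = _index_for(ref, k=8)
    long_segs = [s for s in ref.segments if len(s.sequence) >= read_length]
    if mode in ("germline", "shuffled") and not long_segs:
        raise ValueError("no germline segment is as long as read_length")
    weights = np.array([len(s.sequence) for s in long_segs], dtype=float)
    weights /= weights.sum() if len(weights) else 1.0

    out = []
    for i in range(n):
        for _attempt in range(max_regenerate):
            if mode == "germline":
                seg = long_segs[int(rng.choice(len(long_segs), p=weights))]
                start = int(rng.integers(0, len(seg.sequence) - read_length + 1))
                seq = seg.sequence[start : start + read_length]
            elif mode == "shuffled":
                seg = long_segs[int(rng.choice(len(long_segs), p=weights))]
                shuffled = _dinucleotide_shuffle(seg.sequence, rng)
                start = int(rng.integers(0, len(shuffled) - read_length + 1))
                seq = shuffled[start : start + read_length]
            else:
                seq = _chimeric_read(ref, read_length, rng)
            calls = raw_calls(seq, index, max_mismatches=0, both_strands=True)
            if mode == "chimeric":
                ok = all(not c.productive for c in calls.values())
            else:
                ok = not calls
            if ok:
                out.append(SequencingRead(read_id=f"decoy_{mode}_{i:07d}", sequence=seq))
                break
        else:
            raise RuntimeError(f"could not build a valid {mode} decoy read")
    return out


def decoy_mix(
    ref: GermlineReference,
    n: int,
    read_length: int,
    rng: np.random.Generator,
    proportions: dict[str, float] | None = None,
) -> list[SequencingRead]:
    """A pooled negative control across the three decoy modes."""
    proportions = proportions or {"germline": 0.6, "shuffled": 0.2, "chimeric": 0.2}
    out: list[SequencingRead] = []
    modes = sorted(proportions)
    counts = {m: int(round(n * proportions[m])) for m in modes}
    counts[modes[-1]] += n - sum(counts.values())
    for m in modes:
        if counts[m] > 0:
            out.extend(decoy_reads(ref, counts[m], read_length, rng, mode=m))
    return out


# ---------------------------------------------------------------------------
# expression-weighted RNA-seq


def generate_background_transcripts(
    n: int,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (500, 3000),
) -> list[tuple[str, str]]:
    """Random non-TCR background transcripts (id, sequence)."""
    return [
        (f"bg_{i:05d}", _random_seq(rng, int(rng.integers(*length_range))))
        for i in range(n)
    ]


def simulate_rnaseq(
    tcr_transcripts: Sequence[RecombinedTranscript],
    background_transcripts: Sequence[tuple[str, str]],
    tcr_fraction: Optional[float],
    depth: int,
    read_length: int,
    rng: np.random.Generator,
    lognormal_sigma: float = 1.5,
) -> SimulatedDataset:
    """Error-free RNA-seq with log-normal expression and known abundances.

    Per-transcript expression is log-normal; if ``tcr_fraction`` is given,
    TCR transcripts are rescaled so that they jointly account for that
    fraction of transcripts.  Reads are uniform error-free fragments drawn
    with replacement, with fragments per transcript proportional to its
    transcript abundance (no length bias).  The realized abundance table is
    reported in TPM (transcript fraction x 1e6).
    """
    if not background_transcripts:
        raise ValueError("background transcript set is empty")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if tcr_fraction is not None and not 0 < tcr_fraction < 1:
        raise ValueError("tcr_fraction must be in (0, 1)")
    names = [t.name for t in tcr_transcripts] + [n for n, _ in background_transcripts]
    seqs = [t.sequence for t in tcr_transcripts] + [s for _, s in background_transcripts]
    is_tcr = np.array([True] * len(tcr_transcripts) + [False] * len(background_transcripts))
    expr = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(seqs))
    if tcr_fraction is not None and is_tcr.any():
        tcr_sum = expr[is_tcr].sum()
        bg_sum = expr[~is_tcr].sum()
        expr[is_tcr] *= (tcr_fraction / (1 - tcr_fraction)) * bg_sum / tcr_sum
    frac = expr / expr.sum()
    tpm = frac * 1e6
    picks = rng.choice(len(seqs), size=depth, p=frac)
    reads = []
    for ri, ti in enumerate(picks):
        seq = seqs[ti]
        if len(seq) <= read_length:
            frag = seq
        else:
            start = int(rng.integers(0, len(seq) - read_length + 1))
            frag = seq[start : start + read_length]
        reads.append(
            SequencingRead(
                read_id=f"sim_{ri:09d}", sequence=frag, source_transcript=names[ti],
                flagged_short=len(seq) < read_length,
            )
        )
    table = pd.DataFrame({"transcript_id": names, "tpm": tpm, "is_tcr": is_tcr})
    return SimulatedDataset(
        reads=reads, read_length=read_length, depth=depth, abundance_table=table
    )
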