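"""Junction diversity model for V(D)J recombination.

Nucleotide trimming (exonuclease chew-back) and non-templated (N) additions
at the recombining junctions are drawn from finite discrete distributions.
The published repertoire-derived frequencies behind this process are not
printed anywhere usable, so the defaults are fully specified stand-ins that
reproduce a realistic CDR3 length spread: per-end deletions follow a
truncated geometric(p=0.25) on 0..12 and per-junction insertion counts a
truncated Poisson(lambda=4) on 0..15, with insertion bases uniform over
A/C/G/T.  All three distributions can be overridden from a TSV file.

The alpha chain has no D segment; the number of bases inserted at its
single V-J junction is the rounded arithmetic mean of one sampled V-D count
and one sampled D-J count, i.e. alpha junctions average the two beta
junction draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

_NT = "ACGT"


def _normalized(d: dict[int, float]) -> dict[int, float]:
    total = sum(d.values())
    return {k: v / total for k, v in sorted(d.items())}


def default_deletion_dist(p: float = 0.25, max_del: int = 12) -> dict[int, float]:
    return _normalized({k: p * (1 - p) ** k for k in range(max_del + 1)})


def default_insertion_dist(lam: float = 4.0, max_ins: int = 15) -> dict[int, float]:
    return _normalized({k: float(stats.poisson.pmf(k, lam)) for k in range(max_ins + 1)})


@dataclass
class JunctionModel:
    """Distributions over trims, insertion counts, and insertion bases."""

    deletion_dist: dict[int, float]
    insertion_dist: dict[int, float]
    insertion_base_probs: dict[str, float]

    @classmethod
    def default(cls) -> "JunctionModel":
        return cls(
            deletion_dist=default_deletion_dist(),
            insertion_dist=default_insertion_dist(),
            insertion_base_probs={b: 0.25 for b in _NT},
        )

    def validate(self) -> None:
        for name, dist in (
            ("deletion_dist", self.deletion_dist),
            ("insertion_dist", self.insertion_dist),
        ):
            if not dist:
                raise ValueError(f"{name} is empty")
            if any((not isinstance(k, (int, np.integer))) or k < 0 for k in dist):
                raise ValueError(f"{name} support must be non-negative integers")
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
            if not math.isclose(sum(dist.values()), 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"{name} does not sum to 1")
        if set(self.insertion_base_probs) != set(_NT):
            raise ValueError("insertion_base_probs must cover exactly A/C/G/T")
        if not math.isclose(
            sum(self.insertion_base_probs.values()), 1.0, rel_tol=0, abs_tol=1e-9
        ):
            raise ValueError("insertion_base_probs does not sum to 1")

    def validate_against(self, reference) -> None:
        """Deletion support must fit single-end-trimmed segments (V, J).

        D segments are trimmed at both ends and handled by resampling in
        ``recombine`` instead, so they are not constrained here.
        """
        self.validate()
        max_del = max(self.deletion_dist)
        shortest = reference.min_length(("V", "J"))
        if max_del >= shortest:
            raise ValueError(
                f"deletion support max {max_del} >= shortest V/J segment ({shortest} nt)"
            )

    # -- sampling -----------------------------------------------------------
    def _sample(self, dist: dict[int, float], rng: np.random.Generator) -> int:
        keys = np.fromiter(dist.keys(), dtype=int)
        probs = np.fromiter(dist.values(), dtype=float)
        return int(rng.choice(keys, p=probs))

    def sample_deletion(self, rng: np.random.Generator) -> int:
        return self._sample(self.deletion_dist, rng)

    def sample_insertion_length(self, rng: np.random.Generator) -> int:
        return self._sample(self.insertion_dist, rng)

    def sample_insertion(self, rng: np.random.Generator, length: int) -> str:
        bases = sorted(self.insertion_base_probs)
        probs = [self.insertion_base_probs[b] for b in bases]
        return "".join(rng.choice(bases, size=length, p=probs)) if length else ""

    # -- serialization ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for k, p in self.deletion_dist.items():
            rows.append(("deletion", k, p))
        for k, p in self.insertion_dist.items():
            rows.append(("insertion", k, p))
        for b, p in sorted(self.insertion_base_probs.items()):
            rows.append(("insertion_base", b, p))
        pd.DataFrame(rows, columns=["distribution_name", "value", "probability"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "JunctionModel":
        df = pd.read_csv(path, sep="\t")
        deletion = {
            int(r.value): float(r.probability)
            for r in df[df.distribution_name == "deletion"].itertuples()
        }
        insertion = {
            int(r.value): float(r.probability)
            for r in df[df.distribution_name == "insertion"].itertuples()
        }
        bases = {
            str(r.value): float(r.probability)
            for r in df[df.distribution_name == "insertion_base"].itertuples()
        }
        model = cls(deletion, insertion, bases)
        model.validate()
        return model


@dataclass(frozen=True)
class JunctionEvent:
    """A realized junction: per-end trims plus non-templated insert strings."""

    chain: str
    del_v3: int
    del_j5: int
    del_d5: int | None = None
    del_d3: int | None = None
    ins_vd: str | None = None  # beta V-D junction
    ins_dj: str | None = None  # beta D-J junction
    ins_vj: str | None = None  # alpha V-J junction

    def validate(self, model: JunctionModel) -> None:
        support = set(model.deletion_dist)
        trims = [self.del_v3, self.del_j5]
        if self.chain == "beta":
            trims += [self.del_d5, self.del_d3]
        for t in trims:
            if t not in support:
                raise ValueError(f"deletion count {t} outside model support")
        for ins in (self.ins_vd, self.ins_dj, self.ins_vj):
            if ins is not None and set(ins) - set(_NT):
                raise ValueError(f"insertion {ins!r} contains non-ACGT characters")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_junction(
    model: JunctionModel, chain: str, rng: np.random.Generator
) -> JunctionEvent:
    """Draw one junction event.

    Beta events carry independent V-D and D-J insertions plus four trims.
    Alpha events carry a single V-J insertion whose length is the rounded
    mean of one V-D draw and one D-J draw.
    """
    if chain == "beta":
        return JunctionEvent(
            chain="beta",
            del_v3=model.sample_deletion(rng),
            del_d5=model.sample_deletion(rng),
            del_d3=model.sample_deletion(rng),
            del_j5=model.sample_deletion(rng),
            ins_vd=model.sample_insertion(rng, model.sample_insertion_length(rng)),
            ins_dj=model.sample_insertion(rng, model.sample_insertion_length(rng)),
        )
    if chain == "alpha":
        n_vd = model.sample_insertion_length(rng)
        n_dj = model.sample_insertion_length(rng)
        n = _round_half_up((n_vd + n_dj) / 2)
        return JunctionEvent(
            chain="alpha",
            del_v3=model.sample_deletion(rng),
            del_j5=model.sample_deletion(rng),
            ins_vj=model.sample_insertion(rng, n),
        )
    raise ValueError(f"unknown chain {chain!r}")
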