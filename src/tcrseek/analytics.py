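"""Downstream repertoire statistics.

Given per-individual clonotype tables this module computes: tumor/normal
overlap summaries, cross-individual CDR3 sharing profiles, a randomization
test for recurrent alpha-beta pair co-occurrence, greedy CDR3 clustering at
an identity threshold (CD-HIT-style), and a resampling test asking whether
individuals sharing a CDR3 cluster also share a peptide-MHC more often than
chance.

Identity between two CDR3 amino-acid sequences is defined as the number of
matching positions under an end-anchored (N-terminal-aligned) ungapped
comparison divided by the length of the shorter sequence.  CDR3s are short
and length-similar, where this coincides with a global identity; the
divergence from CD-HIT's internal definition is deliberate and documented.

All randomization p values are plain proportions of null statistics at
least as extreme as the observed one; the smallest representable p is
1/n_iterations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .extractor import ClonotypeTable


@dataclass
class Repertoire:
    """One individual's clonotypes (nucleotide level, both chains)."""

    individual_id: str
    tissue_label: str  # "tumor" or "normal"
    df: pd.DataFrame  # columns: chain, cdr3_nt, cdr3_aa, read_count

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValueError("individual_id must be non-empty")
        if self.tissue_label not in ("tumor", "normal"):
            raise ValueError(f"unknown tissue label {self.tissue_label!r}")
        bad = self.df.cdr3_aa.astype(str).str.contains(r"\*|[a-z]", regex=True)
        if bad.any():
            raise ValueError("amino-acid CDR3s must be uppercase and stop-free")

    @classmethod
    def from_clonotype_table(
        cls, individual_id: str, tissue_label: str, table: ClonotypeTable
    ) -> "Repertoire":
        df = table.df[["chain", "cdr3_nt", "cdr3_aa", "read_count"]].copy()
        return cls(individual_id=individual_id, tissue_label=tissue_label, df=df)

    def aa_set(self, chain: str) -> set[str]:
        return set(self.df[self.df.chain == chain].cdr3_aa)


def overlap_summary(
    pairs: Sequence[tuple[Repertoire, Repertoire]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor/normal overlap of amino-acid clonotypes pooled across pairs.

    Each element of ``pairs`` is a (tumor, normal) repertoire couple from
    the same individual.  Returns (per-chain summary with tumor_only /
    normal_only / shared counts, per-CDR3 table with read counts in each
    tissue and the number of individuals carrying it).
    """
    for tumor, normal in pairs:
        if tumor.individual_id != normal.individual_id:
            raise ValueError(
                f"mismatched pair: {tumor.individual_id} vs {normal.individual_id}"
            )
        if tumor.tissue_label != "tumor" or normal.tissue_label != "normal":
            raise ValueError("pairs must be (tumor, normal) in that order")
    chains = sorted(
        {c for t, n in pairs for c in itertools.chain(t.df.chain, n.df.chain)}
    )
    per_cdr3_rows = []
    summary_rows = []
    for chain in chains:
        tumor_sets = [t.aa_set(chain) for t, _ in pairs]
        normal_sets = [n.aa_set(chain) for _, n in pairs]
        tumor_all = set().union(*tumor_sets) if tumor_sets else set()
        normal_all = set().union(*normal_sets) if normal_sets else set()
        shared = tumor_all & normal_all
        summary_rows.append(
            {
                "chain": chain,
                "tumor_only": len(tumor_all - normal_all),
                "normal_only": len(normal_all - tumor_all),
                "shared": len(shared),
            }
        )
        reads_tumor: dict[str, int] = {}
        reads_normal: dict[str, int] = {}
        individuals: dict[str, set[str]] = {}
        for t, n in pairs:
            for rep, acc in ((t, reads_tumor), (n, reads_normal)):
                sub = rep.df[rep.df.chain == chain]
                for aa, count in zip(sub.cdr3_aa, sub.read_count):
                    acc[aa] = acc.get(aa, 0) + int(count)
                    individuals.setdefault(aa, set()).add(rep.individual_id)
        for aa in sorted(tumor_all | normal_all):
            per_cdr3_rows.append(
                {
                    "chain": chain, "cdr3_aa": aa,
                    "reads_tumor": reads_tumor.get(aa, 0),
                    "reads_normal": reads_normal.get(aa, 0),
                    "n_individuals": len(individuals.get(aa, set())),
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(per_cdr3_rows)


def sharing_profile(
    repertoires: Sequence[Repertoire],
    known_specificities: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-CDR3 sharing across individuals (exact amino-acid matches).

    Returns one row per (chain, cdr3_aa) with the number of individuals
    carrying it, the number of distinct nucleotide variants observed, and
    total reads.  ``known_specificities`` optionally labels sequences with
    a known antigen specificity (e.g. published viral-specific CDR3s).
    """
    if len(repertoires) < 2:
        raise ValueError("sharing requires at least two individuals")
    rows: dict[tuple[str, str], dict] = {}
    for rep in repertoires:
        for r in rep.df.itertuples():
            key = (r.chain, r.cdr3_aa)
            entry = rows.setdefault(
                key, {"individuals": set(), "nt": set(), "reads": 0}
            )
            entry["individuals"].add(rep.individual_id)
            entry["nt"].add(r.cdr3_nt)
            entry["reads"] += int(r.read_count)
    out = pd.DataFrame(
        [
            {
                "chain": chain, "cdr3_aa": aa,
                "n_individuals": len(e["individuals"]),
                "n_nt_variants": len(e["nt"]),
                "total_reads": e["reads"],
                "specificity": (known_specificities or {}).get(aa, ""),
            }
            for (chain, aa), e in sorted(rows.items())
        ]
    )
    return out


@dataclass
class PairSharingResult:
    n_observed_recurrent_pairs: int
    null_counts: list[int]
    p_value: float
    n_iterations: int


def _recurrent_pair_count(
    alpha_sets: Sequence[frozenset], beta_sets: Sequence[frozenset]
) -> int:
    """Distinct (alpha, beta) pairs occurring in >= 2 individuals."""
    seen_once: set[tuple[str, str]] = set()
    recurrent: set[tuple[str, str]] = set()
    for alphas, betas in zip(alpha_sets, beta_sets):
        pairs = {(a, b) for a in alphas for b in betas}
        recurrent |= pairs & seen_once
        seen_once |= pairs
    return len(recurrent)


def pair_cooccurrence_test(
    repertoires: Sequence[Repertoire],
    n_iterations: int = 100,
    rng: Optional[np.random.Generator] = None,
    permute_both: bool = False,
) -> PairSharingResult:
    """Randomization test for recurrent alpha-beta pair co-occurrence.

    Each individual contributes all pairwise combinations of its alpha and
    beta amino-acid CDR3s; the statistic is the number of distinct pairs
    found in at least two individuals.  The null permutes which individual
    owns which beta repertoire (alpha ownership fixed; ``permute_both``
    additionally permutes alpha ownership), and the p value is the
    proportion of iterations with at least the observed degree of sharing.
    """
    rng = rng if rng is not None else np.random.default_rng()
    eligible = [
        r for r in repertoires
        if not r.df[r.df.chain == "alpha"].empty
        and not r.df[r.df.chain == "beta"].empty
    ]
    if len(eligible) < 2:
        raise ValueError("need >= 2 individuals with both chains")
    alpha_sets = [frozenset(r.aa_set("alpha")) for r in eligible]
    beta_sets = [frozenset(r.aa_set("beta")) for r in eligible]
    observed = _recurrent_pair_count(alpha_sets, beta_sets)
    null_counts = []
    n = len(eligible)
    for _ in range(n_iterations):
        beta_perm = [beta_sets[i] for i in rng.permutation(n)]
        if permute_both:
            alpha_perm = [alpha_sets[i] for i in rng.permutation(n)]
        else:
            alpha_perm = alpha_sets
        null_counts.append(_recurrent_pair_count(alpha_perm, beta_perm))
    p = float(np.mean([c >= observed for c in null_counts]))
    return PairSharingResult(
        n_observed_recurrent_pairs=observed,
        null_counts=null_counts, p_value=p, n_iterations=n_iterations,
    )


# ---------------------------------------------------------------------------
# clustering


@dataclass
class CDR3Cluster:
    representative: str
    members: list[tuple[str, str]]  # (individual_id, sequence)
    identity_threshold: float

    def individuals(self) -> set[str]:
        return {ind for ind, _ in self.members}


def sequence_identity(a: str, b: str) -> float:
    """Matches over the shorter length, end-anchored ungapped comparison."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / n


def cluster_cdr3(
    sequences: Sequence[tuple[str, str]],
    identity: float = 0.95,
    word_length: int = 5,
    min_length: int = 6,
) -> list[CDR3Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are sorted longest-first (ties lexicographic) and each joins
    the first-founded cluster whose representative it matches at
    ``identity`` or better, else founds a new cluster; the representative
    is therefore always the longest member.  A shared-word prefilter skips
    representatives with no ``word_length``-mer in common.  Sequences
    shorter than ``min_length`` are discarded (CD-HIT's throw-away rule).
    """
    retained = [(ind, seq) for ind, seq in sequences if len(seq) >= min_length]
    ordered = sorted(retained, key=lambda t: (-len(t[1]), t[1], t[0]))
    clusters: list[CDR3Cluster] = []
    rep_words: list[set[str]] = []

    def words(seq: str) -> set[str]:
        if len(seq) < word_length:
            return {seq}
        return {seq[i : i + word_length] for i in range(len(seq) - word_length + 1)}

    for ind, seq in ordered:
        w = words(seq)
        placed = False
        for ci, cluster in enumerate(clusters):
            if not (w & rep_words[ci]):
                continue
            if sequence_identity(cluster.representative, seq) >= identity:
                cluster.members.append((ind, seq))
                placed = True
                break
        if not placed:
            clusters.append(
                CDR3Cluster(
                    representative=seq, members=[(ind, seq)],
                    identity_threshold=identity,
                )
            )
            rep_words.append(w)
    return clusters


def clusters_to_frame(clusters: Sequence[CDR3Cluster]) -> pd.DataFrame:
    rows = []
    for ci, cluster in enumerate(clusters):
        for ind, seq in cluster.members:
            rows.append(
                {
                    "cluster": ci, "representative": cluster.representative,
                    "individual_id": ind, "cdr3_aa": seq,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pMHC sharing


@dataclass
class PMHCSharingResult:
    n_qualifying_clusters: int
    n_two_individual_clusters: int
    raw_fraction: float
    adjusted_p: float
    n_trials: int


def pmhc_sharing_test(
    clusters: Sequence[CDR3Cluster],
    pmhc: dict[str, set[str]],
    n_trials: int = 1_000_000,
    rng: Optional[np.random.Generator] = None,
) -> PMHCSharingResult:
    """Do individuals sharing a CDR3 cluster also share a peptide-MHC?

    Qualifying clusters contain sequences from >= 2 individuals, at least
    two of whom share a pMHC.  The null repeatedly samples two distinct
    individuals and asks how often they share a pMHC; that fraction times
    the number of multi-individual clusters (a Bonferroni-style correction,
    capped at 1) is the adjusted p value.
    """
    if not pmhc:
        raise ValueError("pMHC table is empty")
    rng = rng if rng is not None else np.random.default_rng()
    individuals = sorted(pmhc)
    if len(individuals) < 2:
        raise ValueError("need >= 2 individuals in the pMHC table")
    # individual x pMHC incidence -> symmetric sharing matrix
    all_pmhc = sorted(set().union(*pmhc.values()))
    pm_index = {p: i for i, p in enumerate(all_pmhc)}
    M = np.zeros((len(individuals), len(all_pmhc)), dtype=bool)
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    for ind, pmset in pmhc.items():
        for p in pmset:
            M[ind_index[ind], pm_index[p]] = True
    shares = (M.astype(np.int32) @ M.astype(np.int32).T) > 0

    multi = [c for c in clusters if len(c.individuals()) >= 2]
    qualifying = 0
    for cluster in multi:
        inds = [i for i in cluster.individuals() if i in ind_index]
        found = any(
            shares[ind_index[a], ind_index[b]]
            for a, b in itertools.combinations(inds, 2)
        )
        if found:
            qualifying += 1

    i1 = rng.integers(0, len(individuals), size=n_trials)
    i2 = rng.integers(0, len(individuals) - 1, size=n_trials)
    i2 = np.where(i2 >= i1, i2 + 1, i2)  # distinct pair, uniform
    raw_fraction = float(np.mean(shares[i1, i2]))
    adjusted = min(1.0, raw_fraction * len(multi))
    return PMHCSharingResult(
        n_qualifying_clusters=qualifying,
        n_two_individual_clusters=len(multi),
        raw_fraction=raw_fraction,
        adjusted_p=adjusted,
        n_trials=n_trials,
    )


def load_pmhc_table(path) -> dict[str, set[str]]:
    """TSV (individual_id, hla_allele, peptide) -> per-individual pMHC sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.individual_id, set()).add(f"{r.hla_allele}|{r.peptide}")
    return out
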