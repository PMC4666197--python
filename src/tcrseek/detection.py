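"""Logistic model of CDR3 detection probability.

The chance of recovering a given CDR3 from an RNA-seq dataset is modelled
as a logistic function of four covariates: log10 transcript abundance
(TPM), sequencing depth in tens of millions of reads, read length in nt,
and CDR3 length in nt:

    logit P(detected) = b0 + b1*log10(TPM) + b2*(depth/1e7) + b3*L + b4*c

The published fit (b0, .., b4) = (-5.38, +1.98, +0.51, +0.04, -0.04) is
available as :data:`PUBLISHED_COEFFICIENTS`; the model can also be refit on
detection records produced by the package's own benchmark.  Two structural
requirements gate a record's eligibility for modelling: the transcript must
be expressed (TPM > 0) and the read length must exceed the CDR3 length.

The same linear predictor is inverted in closed form to answer the applied
question "how deep must I sequence to have probability p of seeing this
CDR3?", and a small helper converts percent T cell infiltration into the
expected TCR transcript fraction (whole blood carries roughly one TCR
transcript per 2000; lymphocytes are 20-40 % of white blood cells).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .extractor import ClonotypeTable
from .vdj import RecombinedTranscript

RECORD_COLUMNS = [
    "transcript_id", "tpm", "depth", "read_length", "cdr3_length", "detected"
]


@dataclass(frozen=True)
class DetectionModelCoefficients:
    intercept: float
    b_log10_tpm: float
    b_depth_per_1e7: float
    b_read_length: float
    b_cdr3_length: float

    def linear_predictor(
        self, tpm: float, depth: float, read_length: float, cdr3_length: float
    ) -> float:
        if tpm <= 0:
            raise ValueError("tpm must be > 0 (log10 undefined otherwise)")
        return (
            self.intercept
            + self.b_log10_tpm * math.log10(tpm)
            + self.b_depth_per_1e7 * (depth / 1e7)
            + self.b_read_length * read_length
            + self.b_cdr3_length * cdr3_length
        )

    def odds_ratios(self) -> dict[str, float]:
        return {
            "log10_tpm": math.exp(self.b_log10_tpm),
            "depth_per_1e7": math.exp(self.b_depth_per_1e7),
            "read_length": math.exp(self.b_read_length),
            "cdr3_length": math.exp(self.b_cdr3_length),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectionModelCoefficients":
        return cls(**json.loads(Path(path).read_text()))


#: The published multivariate fit.
PUBLISHED_COEFFICIENTS = DetectionModelCoefficients(
    intercept=-5.38,
    b_log10_tpm=1.98,
    b_depth_per_1e7=0.51,
    b_read_length=0.04,
    b_cdr3_length=-0.04,
)


def predict_detection(
    coeffs: DetectionModelCoefficients,
    tpm: float,
    depth: float,
    read_length: float,
    cdr3_length: float,
) -> float:
    """Inverse-logit of the linear predictor."""
    lp = coeffs.linear_predictor(tpm, depth, read_length, cdr3_length)
    return 1.0 / (1.0 + math.exp(-lp))


def min_depth_for_detection(
    coeffs: DetectionModelCoefficients,
    tpm: float,
    read_length: float,
    cdr3_length: float,
    target_p: float = 0.5,
    granularity: float = 1e7,
) -> tuple[float, float]:
    """Closed-form depth at which detection probability reaches ``target_p``.

    Returns ``(exact_depth, depth rounded up to granularity)``; the default
    granularity of 1e7 reads matches the resolution at which sequencing
    depth requirements are usually quoted.
    """
    if coeffs.b_depth_per_1e7 <= 0:
        raise ValueError("depth coefficient must be positive to solve upward")
    if not 0 < target_p < 1:
        raise ValueError("target_p must be in (0, 1)")
    if tpm <= 0:
        raise ValueError("tpm must be > 0")
    rest = (
        coeffs.intercept
        + coeffs.b_log10_tpm * math.log10(tpm)
        + coeffs.b_read_length * read_length
        + coeffs.b_cdr3_length * cdr3_length
    )
    logit = math.log(target_p / (1 - target_p))
    exact = (logit - rest) / coeffs.b_depth_per_1e7 * 1e7
    rounded = math.ceil(exact / granularity) * granularity
    return exact, rounded


def til_to_tcr_fraction(
    til_percent: float,
    blood_tcr_fraction: float = 1.5e-4,
    lymphocyte_fraction: float = 0.3,
) -> float:
    """Expected TCR transcript fraction for a given percent T cell infiltration.

    ``blood_tcr_fraction`` is the TCR transcript fraction of healthy whole
    blood; dividing by the lymphocyte proportion of white blood cells
    (default 0.3, the midpoint of 20-40 %) gives the fraction for a pure
    lymphocyte population, which is then scaled by the infiltration
    percentage.
    """
    if not 0 <= til_percent <= 100:
        raise ValueError("til_percent must be within [0, 100]")
    if not 0 < lymphocyte_fraction <= 1:
        raise ValueError("lymphocyte_fraction must be in (0, 1]")
    pure = blood_tcr_fraction / lymphocyte_fraction
    return pure * til_percent / 100.0


def fraction_to_tpm(fraction: float) -> float:
    """Transcript fraction -> transcripts per million."""
    return fraction * 1e6


def build_detection_records(
    transcripts: Sequence[RecombinedTranscript],
    abundance_table: pd.DataFrame,
    extracted: ClonotypeTable,
    depth: int,
    read_length: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One detection record per truth transcript.

    ``detected`` is an exact nucleotide membership test of the transcript's
    truth CDR3 against the extracted table (same chain).  Records violating
    either modelling criterion — zero abundance, or CDR3 length not shorter
    than the read length — are split into the returned side table.
    """
    tpm_by_id = dict(
        zip(abundance_table.transcript_id, abundance_table.tpm)
    )
    sets_by_chain = {
        chain: extracted.cdr3_nt_set(chain)
        for chain in {t.chain for t in transcripts}
    }
    rows = []
    for t in transcripts:
        if t.cdr3_nt is None:
            raise ValueError(f"{t.name}: transcript lacks truth CDR3")
        extracted_set = sets_by_chain[t.chain]
        rows.append(
            {
                "transcript_id": t.name,
                "tpm": float(tpm_by_id.get(t.name, 0.0)),
                "depth": depth,
                "read_length": read_length,
                "cdr3_length": len(t.cdr3_nt),
                "detected": t.cdr3_nt in extracted_set,
            }
        )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    eligible = (df.tpm > 0) & (df.read_length > df.cdr3_length)
    return df[eligible].reset_index(drop=True), df[~eligible].reset_index(drop=True)


def fit_detection_model(
    records: pd.DataFrame,
    split_seed: int = 0,
    cutoff: float = 0.5,
) -> tuple[DetectionModelCoefficients, dict]:
    """Fit the four-covariate logistic model on a random half of the records.

    The other half is scored at probability ``cutoff`` to report validation
    sensitivity and specificity.  Complete separation (or a training half
    with only one outcome class) raises with a diagnostic.
    """
    df = records.reset_index(drop=True)
    y = df.detected.astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError(
            "degenerate records: all detected or all undetected (complete separation)"
        )
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(len(df))
    half = len(df) // 2
    train_idx, val_idx = perm[:half], perm[half:]

    def design(idx):
        sub = df.iloc[idx]
        X = np.column_stack(
            [
                np.log10(sub.tpm.to_numpy()),
                sub.depth.to_numpy() / 1e7,
                sub.read_length.to_numpy(),
                sub.cdr3_length.to_numpy(),
            ]
        )
        return sm.add_constant(X, has_constant="add"), sub.detected.astype(float).to_numpy()

    X_train, y_train = design(train_idx)
    if y_train.min() == y_train.max():
        raise ValueError("training half contains a single outcome class")
    try:
        fit = sm.GLM(y_train, X_train, family=sm.families.Binomial()).fit()
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    if not np.all(np.isfinite(fit.params)):
        raise ValueError("logistic fit diverged: non-finite coefficients")
    coeffs = DetectionModelCoefficients(
        intercept=float(fit.params[0]),
        b_log10_tpm=float(fit.params[1]),
        b_depth_per_1e7=float(fit.params[2]),
        b_read_length=float(fit.params[3]),
        b_cdr3_length=float(fit.params[4]),
    )
    X_val, y_val = design(val_idx)
    p_val = fit.predict(X_val)
    pred = p_val >= cutoff
    tp = int(np.sum(pred & (y_val == 1)))
    tn = int(np.sum(~pred & (y_val == 0)))
    fn = int(np.sum(~pred & (y_val == 1)))
    fp = int(np.sum(pred & (y_val == 0)))
    performance = {
        "n_train": int(half),
        "n_validation": int(len(df) - half),
        "validation_sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "validation_specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "cutoff": cutoff,
    }
    return coeffs, performance
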