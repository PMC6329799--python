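"""Isoform, signature and stratification scores for AML patient cohorts.

Implements the patient-level summaries used downstream of RNA-seq
quantification:

* transcript-set scores — log2 of the summed expression of a fixed set
  of Ensembl transcripts.  Built-in sets cover the anti-apoptotic BCL2L1
  long isoform (BCL-XL), the pro-apoptotic short isoform (BCL-XS) and
  the exon-12-including BIN1 isoforms, whose protein product cannot
  inhibit MYC;
* the BCL2L1 L/S log-ratio, a per-patient summary of apoptotic balance;
* a MYC-target signature score — the average log2 expression of the
  signature genes, each normalized to the patient's own MYC expression
  so that global differences in MYC level (or library size) cancel;
* Z-score normalization, extreme-quantile and median stratification,
  and the Mann-Whitney U comparison between patient groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class TranscriptMatrix:
    """transcript x patient expression (non-negative, linear scale)."""

    expr: pd.DataFrame
    tx2gene: dict[str, str]

    def __post_init__(self) -> None:
        if (self.expr.to_numpy() < 0).any():
            raise ValueError("expression must be non-negative")

    @property
    def patients(self) -> list[str]:
        return list(self.expr.columns)


@dataclass(frozen=True)
class TranscriptSetScore:
    """A named sum-of-transcripts score, optionally log2-transformed."""

    name: str
    transcript_ids: tuple[str, ...]
    log2_transform: bool = True
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not self.transcript_ids:
            raise ValueError("transcript_ids must be non-empty")


# Ensembl transcript sets behind the built-in isoform scores.
BCL2L1_L = TranscriptSetScore(
    "BCL2L1_L", ("ENST00000307677", "ENST00000376062")
)
BCL2L1_S = TranscriptSetScore("BCL2L1_S", ("ENST00000376055",))
BIN1_PLUS12 = TranscriptSetScore(
    "BIN1_plus12",
    (
        "ENST00000259238",
        "ENST00000316724",
        "ENST00000346226",
        "ENST00000393040",
        "ENST00000484253",
    ),
)
BUILTIN_SCORES: dict[str, TranscriptSetScore] = {
    s.name: s for s in (BCL2L1_L, BCL2L1_S, BIN1_PLUS12)
}


def transcript_set_score(tm: TranscriptMatrix, spec: TranscriptSetScore) -> pd.Series:
    """Per-patient sum over the set's transcripts (log2(sum + pc) if set).

    Transcripts absent from the matrix contribute zero with a warning;
    if every transcript is missing the score is undefined and raises.
    """
    present = [t for t in spec.transcript_ids if t in tm.expr.index]
    missing = [t for t in spec.transcript_ids if t not in tm.expr.index]
    if not present:
        raise ValueError(f"{spec.name}: none of the transcripts are in the matrix")
    if missing:
        log.warning("%s: treating missing transcript(s) %s as zero", spec.name, missing)
    total = tm.expr.loc[present].sum(axis=0)
    if spec.log2_transform:
        total = np.log2(total + spec.pseudocount)
    total.name = spec.name
    return total


def bcl2l1_ratio(tm: TranscriptMatrix, pseudocount: float = 0.0) -> pd.Series:
    """log2 BCL2L1-L/S ratio per patient: log2((sum L + pc) / (S + pc)).

    The default pseudocount of 0 keeps the log identities exact (doubling
    the L transcripts shifts the ratio by exactly +1); pass a positive
    pseudocount for matrices containing zeros.
    """
    l_spec = TranscriptSetScore("BCL2L1_L", BCL2L1_L.transcript_ids, True, pseudocount)
    s_spec = TranscriptSetScore("BCL2L1_S", BCL2L1_S.transcript_ids, True, pseudocount)
    num = transcript_set_score(tm, l_spec)
    den = transcript_set_score(tm, s_spec)
    if not np.isfinite(den).all() or not np.isfinite(num).all():
        raise ValueError("zero expression with pseudocount 0; pass pseudocount > 0")
    out = num - den
    out.name = "BCL2L1_ratio"
    return out


def zscore(values: pd.Series) -> pd.Series:
    """Standardize to mean 0 and sample standard deviation 1 (n-1 denominator)."""
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (values - values.mean()) / sd


def quantile_groups(
    stratifier: pd.Series, fraction: float
) -> tuple[list[str], list[str]]:
    """Extreme-quantile patient groups, e.g. the 10% lowest vs. highest.

    Each group holds floor(n * fraction) patients; boundary ties are
    broken by patient id and the groups never overlap.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(stratifier)
    k = int(np.floor(n * fraction))
    if k < 1:
        raise ValueError("fraction too small: empty groups")
    if 2 * k > n:
        raise ValueError("groups would overlap")
    order = stratifier.reset_index()
    order.columns = ["patient_id", "value"]
    order = order.sort_values(["value", "patient_id"])
    low = list(order["patient_id"].iloc[:k])
    high = list(order["patient_id"].iloc[-k:])
    return low, high


def median_split(values: pd.Series) -> tuple[list[str], list[str]]:
    """Split patients at the median; values equal to the median go low.

    The low/high assignment of exact-median patients is deterministic and
    logged; a constant vector yields an empty high group with a warning.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    med = float(np.median(values))
    low = sorted(values.index[values <= med])
    high = sorted(values.index[values > med])
    n_at = int((values == med).sum())
    if n_at:
        log.info("median_split: %d value(s) equal to the median assigned low", n_at)
    if not high:
        log.warning("median_split: constant (or degenerate) input, empty high group")
    return low, high


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison between two patient groups."""

    n_low: int
    n_high: int
    U: float
    p_two_sided: float
    method: Literal["EXACT", "NORMAL_APPROX"]


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when n_a + n_b <= 12 with no ties in the
    pooled sample, otherwise the normal approximation with midrank tie
    correction and continuity correction.  U is the statistic of the
    first sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 12 and no_ties:
        method = "EXACT"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "NORMAL_APPROX"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return GroupComparison(
        n_low=len(a),
        n_high=len(b),
        U=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method=method,
    )


def myc_signature_score(
    expr: pd.DataFrame,
    signature: Iterable[str],
    reference_gene: str = "MYC",
    pseudocount: float = 0.0,
) -> pd.Series:
    """Average log2 expression of the signature genes, MYC-normalized.

    score_p = mean_g log2((expr[g,p] + pc) / (expr[ref,p] + pc)).  The
    normalization removes confounding differences in MYC expression (and,
    with pseudocount 0, the score is exactly invariant to any per-patient
    global rescaling of expression).  Signature genes absent from the
    matrix are dropped with a warning; a missing reference gene raises.
    """
    if reference_gene not in expr.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from matrix")
    ref = expr.loc[reference_gene] + pseudocount
    if (ref <= 0).any():
        raise ValueError(f"{reference_gene} must be positive in every patient")
    sig = list(dict.fromkeys(signature))
    present = [g for g in sig if g in expr.index and g != reference_gene]
    dropped = [g for g in sig if g not in expr.index]
    if dropped:
        log.warning("signature gene(s) not in matrix, dropped: %s", dropped)
    if not present:
        raise ValueError("no signature gene present in the matrix")
    ratios = np.log2((expr.loc[present] + pseudocount).div(ref, axis=1))
    score = ratios.mean(axis=0)
    score.name = "myc_signature_score"
    return score


def read_signature(path: str | Path) -> list[str]:
    """Read a gene list: one symbol per line, or GMT (first set used)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty signature file")
    first = lines[0].split("\t")
    if len(first) > 2:  # GMT: name, description, genes...
        return [g for g in first[2:] if g]
    return [ln.split("\t")[0] for ln in lines]


def read_transcript_matrix(path: str | Path) -> TranscriptMatrix:
    """TSV with columns transcript_id, gene, then one column per patient."""
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    tx2gene = df["gene"].to_dict()
    return TranscriptMatrix(df.drop(columns="gene"), tx2gene)


def write_transcript_matrix(tm: TranscriptMatrix, path: str | Path) -> None:
    out = tm.expr.copy()
    out.insert(0, "gene", pd.Series(tm.tx2gene).reindex(out.index))
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_gene_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with column gene then one column per patient."""
    return pd.read_csv(path, sep="\t", index_col="gene")
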