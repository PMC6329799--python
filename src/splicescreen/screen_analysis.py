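"""Fold-change analysis and hit calling for dropout/enrichment screens.

The screening logic: raw counts are normalized to each sample's total
(with a pseudocount so zero-output hairpins stay finite), per-replicate
fold changes output/input are divided by a summary (median by default) of
the control hairpins' fold changes, hairpins are ranked by their mean
log2 fold change across replicates, and a gene scores as a hit when
"multiple" (>= ``min_support``) of its hairpins rank within the top
``enrich_pct`` most enriched (or ``deplete_pct`` most depleted) hairpins
in the leukemic arm while the same criterion is NOT met in the normal
counter-screen arm.  Percentile of rank r among N hairpins is r/N with an
inclusive boundary; ties are broken lexicographically by hairpin id so
the whole pipeline is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import Arm, CountMatrix, ShrnaLibrary, Timepoint

log = logging.getLogger(__name__)

ControlSummary = Literal["median", "mean", "none"]


def normalize_counts(cm: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-sample relative frequencies: (count + pc) / sum(count + pc)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = cm.counts.astype(float) + pseudocount
    totals = shifted.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total after pseudocount: {list(zero.index)}")
    return shifted / totals


def fold_change(
    freqs: pd.DataFrame,
    input_sample: str,
    output_sample: str,
    library: ShrnaLibrary,
    control_summary: ControlSummary = "median",
) -> pd.DataFrame:
    """Control-normalized fold change for one replicate.

    ``raw = freq_out / freq_in``; every raw ratio is divided by the
    median (or mean) of the control hairpins' raw ratios, so a hairpin
    behaving like the scrambled controls has fc = 1.  Returns a frame
    with columns norm_input, norm_output, raw, fc, log2fc.
    """
    for s in (input_sample, output_sample):
        if s not in freqs.columns:
            raise KeyError(f"unknown sample {s!r}")
    fin = freqs[input_sample]
    fout = freqs[output_sample]
    if (fin <= 0).any():
        raise ValueError("zero input frequency; use a positive pseudocount")
    raw = fout / fin
    controls = library.control_ids
    if control_summary == "none":
        normalizer = 1.0
    elif not controls:
        raise ValueError(
            "library has no control hairpins; pass control_summary='none' "
            "to use raw output/input ratios"
        )
    elif control_summary == "median":
        normalizer = float(raw.loc[controls].median())
    elif control_summary == "mean":
        normalizer = float(raw.loc[controls].mean())
    else:
        raise ValueError(f"unknown control_summary {control_summary!r}")
    fc = raw / normalizer
    return pd.DataFrame(
        {
            "norm_input": fin,
            "norm_output": fout,
            "raw": raw,
            "fc": fc,
            "log2fc": np.log2(fc),
        }
    )


def mean_log2fc(per_replicate: Sequence[pd.DataFrame]) -> pd.Series:
    """Arithmetic mean of log2 fold changes across replicate tables."""
    if not per_replicate:
        raise ValueError("need at least one replicate")
    idx = per_replicate[0].index
    for t in per_replicate[1:]:
        if not idx.equals(t.index):
            raise ValueError("replicate tables cover different hairpin sets")
    stacked = pd.concat([t["log2fc"] for t in per_replicate], axis=1)
    out = stacked.mean(axis=1)
    out.name = "mean_log2fc"
    return out


def replicate_correlation(rep1: pd.Series, rep2: pd.Series) -> float:
    """Pearson r between two replicate log2 fold-change vectors."""
    if len(rep1) != len(rep2):
        raise ValueError("replicate vectors differ in length")
    if len(rep1) < 3:
        raise ValueError("need at least 3 hairpins")
    if np.std(rep1) == 0 or np.std(rep2) == 0:
        raise ValueError("zero variance in a replicate")
    r, _ = stats.pearsonr(np.asarray(rep1, float), np.asarray(rep2, float))
    return float(r)


def rank_percentiles(mean: pd.Series) -> pd.DataFrame:
    """Enrichment/depletion ranks and percentiles of mean log2 fold change.

    enrich_rank 1 = most enriched, deplete_rank 1 = most depleted;
    percentile = rank / N.  Ties are broken by hairpin id (ascending) in
    both directions, and flagged in the log.
    """
    if len(mean) < 1:
        raise ValueError("empty input")
    n = len(mean)
    if mean.duplicated().any() and mean.nunique() < n:
        ties = int(n - mean.nunique())
        log.info("rank_percentiles: %d tied value(s), breaking ties by hairpin_id", ties)
    df = pd.DataFrame({"mean_log2fc": mean})
    order_enrich = df.reset_index(names="hairpin_id").sort_values(
        by=["mean_log2fc", "hairpin_id"], ascending=[False, True]
    )
    df.loc[order_enrich["hairpin_id"], "enrich_rank"] = np.arange(1, n + 1)
    order_deplete = df.reset_index(names="hairpin_id").sort_values(
        by=["mean_log2fc", "hairpin_id"], ascending=[True, True]
    )
    df.loc[order_deplete["hairpin_id"], "deplete_rank"] = np.arange(1, n + 1)
    df["enrich_rank"] = df["enrich_rank"].astype(int)
    df["deplete_rank"] = df["deplete_rank"].astype(int)
    df["enrich_pctile"] = df["enrich_rank"] / n
    df["deplete_pctile"] = df["deplete_rank"] / n
    return df


@dataclass
class FoldChangeTable:
    """Per-hairpin fold changes, replicate mean and percentile ranks.

    ``summary`` is indexed by hairpin_id with columns gene, is_control,
    mean_log2fc, enrich_rank/deplete_rank and the matching percentiles;
    ``per_replicate`` holds the long-format per-replicate table when the
    table was built from counts.
    """

    summary: pd.DataFrame
    library: ShrnaLibrary
    per_replicate: pd.DataFrame | None = None

    @classmethod
    def from_mean_log2fc(cls, mean: pd.Series, library: ShrnaLibrary) -> "FoldChangeTable":
        ranks = rank_percentiles(mean)
        ranks.insert(0, "gene", library.gene_of().reindex(ranks.index))
        ranks.insert(1, "is_control", library.is_control_of().reindex(ranks.index))
        return cls(summary=ranks, library=library)

    def write(self, path) -> None:
        out = self.summary.copy()
        out.index.name = "hairpin_id"
        out.to_csv(path, sep="\t")


def fold_change_table(
    cm: CountMatrix,
    pseudocount: float = 0.5,
    control_summary: ControlSummary = "median",
) -> FoldChangeTable:
    """Full per-arm pipeline: normalize, per-replicate fold change, mean, ranks.

    The matrix must contain one arm only, with an INPUT and an OUTPUT
    sample per replicate.
    """
    arms = {s.arm for s in cm.samples}
    if len(arms) != 1:
        raise ValueError("fold_change_table expects a single-arm matrix; use cm.for_arm()")
    freqs = normalize_counts(cm, pseudocount)
    tables = []
    long_parts = []
    for rep in cm.replicates:
        pair = {s.timepoint: s.sample_id for s in cm.samples if s.replicate == rep}
        if Timepoint.INPUT not in pair or Timepoint.OUTPUT not in pair:
            raise ValueError(f"replicate {rep} lacks an INPUT/OUTPUT pair")
        t = fold_change(
            freqs, pair[Timepoint.INPUT], pair[Timepoint.OUTPUT], cm.library, control_summary
        )
        tables.append(t)
        lp = t.copy()
        lp.insert(0, "replicate", rep)
        long_parts.append(lp)
    mean = mean_log2fc(tables)
    fct = FoldChangeTable.from_mean_log2fc(mean, cm.library)
    fct.per_replicate = pd.concat(long_parts)
    return fct


@dataclass(frozen=True)
class HitParams:
    """Hit-calling thresholds.

    enrich_pct / deplete_pct: inclusive percentile cuts for the most
    enriched / depleted hairpins; min_support: how many of a gene's
    hairpins must fall inside the cut ("multiple" read as >= 2);
    counter_min_support: support needed for the counter-screen exclusion
    (None = same rule as the main arm; 1 = softer per-hairpin exclusion).
    """

    enrich_pct: float = 0.20
    deplete_pct: float = 0.25
    min_support: int = 2
    pseudocount: float = 0.5
    control_summary: ControlSummary = "median"
    counter_min_support: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.enrich_pct < 1 and 0 < self.deplete_pct < 1):
            raise ValueError("percentile cuts must be in (0, 1)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


def call_hits(
    aml_fc: FoldChangeTable,
    counter_fc: FoldChangeTable,
    library: ShrnaLibrary,
    params: HitParams = HitParams(),
) -> pd.DataFrame:
    """Gene-level hit calls with counter-screen exclusion.

    Returns one row per (gene, direction) with supporting hairpins in the
    leukemic arm, the counter-screen flag, and the final call
    ``called = (n_support >= min_support) and not counter_flag``.
    Control hairpins never contribute to gene-level evaluation.
    """
    a = aml_fc.summary
    c = counter_fc.summary
    if set(a.index) != set(c.index):
        raise ValueError("AML and counter tables cover different hairpin sets")
    c = c.reindex(a.index)
    targeting = ~a["is_control"].astype(bool)
    counter_support = params.counter_min_support or params.min_support
    rows = []
    for direction, col, cut in (
        ("ENRICHED", "enrich_pctile", params.enrich_pct),
        ("DEPLETED", "deplete_pctile", params.deplete_pct),
    ):
        in_cut_a = targeting & (a[col] <= cut)
        in_cut_c = targeting & (c[col] <= cut)
        n_a = in_cut_a.groupby(a["gene"]).sum()
        n_c = in_cut_c.groupby(a["gene"]).sum()
        support_ids = (
            a.index.to_series()[in_cut_a].groupby(a.loc[in_cut_a, "gene"]).apply(sorted)
        )
        for gene in sorted(a.loc[targeting, "gene"].unique()):
            ns = int(n_a.get(gene, 0))
            flag = int(n_c.get(gene, 0)) >= counter_support
            rows.append(
                {
                    "gene": gene,
                    "direction": direction,
                    "n_support": ns,
                    "support_ids": ",".join(support_ids.get(gene, [])),
                    "counter_flag": flag,
                    "called": ns >= params.min_support and not flag,
                }
            )
    hits = pd.DataFrame(rows)
    n_called = hits.groupby("direction")["called"].sum()
    log.info(
        "hit calling: %d enriched, %d depleted genes called",
        int(n_called.get("ENRICHED", 0)), int(n_called.get("DEPLETED", 0)),
    )
    return hits


def called_genes(hits: pd.DataFrame, direction: str | None = None) -> list[str]:
    sel = hits["called"]
    if direction is not None:
        sel = sel & (hits["direction"] == direction)
    return sorted(hits.loc[sel, "gene"])


def analyze_screen(
    cm_aml: CountMatrix,
    cm_counter: CountMatrix,
    params: HitParams = HitParams(),
) -> tuple[FoldChangeTable, FoldChangeTable, pd.DataFrame]:
    """Counts-to-hits convenience pipeline for a two-arm screen."""
    fc_a = fold_change_table(cm_aml, params.pseudocount, params.control_summary)
    fc_c = fold_change_table(cm_counter, params.pseudocount, params.control_summary)
    hits = call_hits(fc_a, fc_c, cm_aml.library, params)
    return fc_a, fc_c, hits


def competitive_ratio(gfp_frac: pd.Series, yfp_frac: pd.Series) -> pd.Series:
    """GFP/YFP ratio over time normalized to the input mixture.

    Both series are fractions in (0, 1) over shared timepoints, the first
    of which is the input mixture; the returned ratio is 1 at input by
    construction.
    """
    if not gfp_frac.index.equals(yfp_frac.index):
        raise ValueError("series must share timepoints")
    for s, name in ((gfp_frac, "gfp"), (yfp_frac, "yfp")):
        if ((s <= 0) | (s >= 1)).any():
            raise ValueError(f"{name} fractions must lie strictly in (0, 1)")
    ratio = gfp_frac / yfp_frac
    out = ratio / ratio.iloc[0]
    out.name = "gfp_yfp_ratio"
    return out
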