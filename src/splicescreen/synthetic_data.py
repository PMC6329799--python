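"""Synthetic screens, reads and patient cohorts with ground-truth labels.

Every downstream stage of the package can be exercised without external
downloads: the generators here emit data with the statistical structure
the analyses assume, alongside a truth table recording what was planted.

Screen counts follow a hierarchical model: per-hairpin input abundances
are log-normal; the expected output abundance multiplies the input by
2^(gene effect + construct effect), where the construct effect is a
hairpin-level normal perturbation shared across replicates AND arms —
it models the physical shRNA (knockdown efficiency, off-target burden),
which is identical wherever the construct is used, not sequencing noise.
Observed counts are negative binomial (overdispersed sequencing).  The
default design mirrors the screen this package analyses: 613 hairpins
over 230 genes in pools of 150, duplicate replicates, with scrambled
controls carrying gene effect zero in both arms.  Default noise levels
(dispersion 0.13 at depth 1000x, construct sd 0.8 log2) are chosen so
the model's expected replicate fold-change correlation is ~0.53, the
reproducibility actually observed in vivo for this design.

Cohorts couple a latent per-patient RBM25 level to isoform scores, a
MYC-target score and survival hazard, with configurable coupling signs
and strengths; expression is emitted on a linear positive scale so the
downstream log2 transforms are meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_io import (
    Arm,
    CountMatrix,
    Read,
    SampleMeta,
    ShrnaLibrary,
    ShrnaRecord,
    Timepoint,
)
from .cohort_scoring import BCL2L1_L, BCL2L1_S, BIN1_PLUS12, TranscriptMatrix

log = logging.getLogger(__name__)

_NT = np.array(list("ACGT"))


@dataclass
class ScreenSimConfig:
    """Design and noise model of a simulated two-arm pooled screen.

    effects maps gene -> (aml_log2_effect, counter_log2_effect); genes
    not listed are neutral.  ``total_hairpins`` (optional) overrides the
    uniform hairpins_per_gene by distributing extra hairpins over the
    first genes until the total is reached, which reproduces designs
    whose hairpin count is not a multiple of the gene count.
    """

    n_genes: int = 230
    hairpins_per_gene: int = 2
    total_hairpins: int | None = 613
    n_controls: int = 12
    pool_size: int = 150
    n_replicates: int = 2
    depth_per_hairpin: float = 1000.0
    dispersion: float = 0.13
    hairpin_efficiency_sd: float = 0.8
    input_lognormal_sd: float = 0.5
    effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.hairpins_per_gene < 1 or self.n_controls < 0:
            raise ValueError("invalid library design")
        if self.total_hairpins is not None:
            lo = self.n_genes * self.hairpins_per_gene
            if not (lo <= self.total_hairpins <= self.n_genes * (self.hairpins_per_gene + 1)):
                raise ValueError(
                    "total_hairpins must lie between n_genes*hairpins_per_gene and "
                    "n_genes*(hairpins_per_gene+1)"
                )
        if self.dispersion < 0 or self.hairpin_efficiency_sd < 0:
            raise ValueError("dispersion and hairpin_efficiency_sd must be >= 0")
        if self.depth_per_hairpin <= 0 or self.n_replicates < 1:
            raise ValueError("invalid depth or replicate count")
        if self.pool_size < 1 or self.pool_size > self.n_hairpins_total:
            raise ValueError("pool_size must be in [1, total hairpins]")
        unknown = set(self.effects) - set(self.gene_names)
        if unknown:
            raise ValueError(f"effects for unknown gene(s): {sorted(unknown)}")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"SF{i + 1:0{width}d}" for i in range(self.n_genes)]

    def hairpins_for_gene(self, i: int) -> int:
        base = self.hairpins_per_gene
        if self.total_hairpins is None:
            return base
        extra = self.total_hairpins - self.n_genes * base
        return base + (1 if i < extra else 0)

    @property
    def n_hairpins_total(self) -> int:
        n_target = (
            self.total_hairpins
            if self.total_hairpins is not None
            else self.n_genes * self.hairpins_per_gene
        )
        return n_target + self.n_controls


def _random_guides(rng: np.random.Generator, n: int, length: int = 21) -> list[str]:
    guides: set[str] = set()
    while len(guides) < n:
        block = rng.integers(0, 4, size=(n - len(guides), length))
        for row in block:
            guides.add("".join(_NT[row]))
    return sorted(guides)[:n]


def make_library(cfg: ScreenSimConfig, rng: np.random.Generator) -> ShrnaLibrary:
    """Build the simulated hairpin library, pools assigned round-robin."""
    records: list[ShrnaRecord] = []
    genes = cfg.gene_names
    guides = iter(_random_guides(rng, cfg.n_hairpins_total))
    for i, gene in enumerate(genes):
        for j in range(cfg.hairpins_for_gene(i)):
            records.append(
                ShrnaRecord(f"{gene}_sh{j + 1}", gene, next(guides), is_control=False)
            )
    for k in range(cfg.n_controls):
        records.append(ShrnaRecord(f"SCR{k + 1:02d}", "", next(guides), is_control=True))
    n_pools = math.ceil(len(records) / cfg.pool_size)
    pools: dict[str, set[str]] = {f"pool{p + 1}": set() for p in range(n_pools)}
    for i, rec in enumerate(records):
        pools[f"pool{i % n_pools + 1}"].add(rec.hairpin_id)
    lib = ShrnaLibrary(records, pools)
    log.info("simulated library: %d hairpins in %d pools %s",
             len(lib), n_pools, lib.pool_sizes())
    return lib


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson as limit)."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion < 1e-9:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Simulate both arms of the screen; returns (AML, counter, truth).

    The truth table has one row per gene with the planted log2 effects
    and a class label: ENRICHED / DEPLETED (AML-specific), CONFOUNDED
    (effect shared with the counter arm) or NEUTRAL.
    """
    rng = np.random.default_rng(cfg.seed)
    library = make_library(cfg, rng)
    ids = library.hairpin_ids
    gene_of = library.gene_of()
    n = len(ids)

    input_abund = rng.lognormal(mean=0.0, sigma=cfg.input_lognormal_sd, size=n)
    construct = rng.normal(0.0, cfg.hairpin_efficiency_sd, size=n)
    effects_a = np.array([cfg.effects.get(gene_of[h], (0.0, 0.0))[0] for h in ids])
    effects_c = np.array([cfg.effects.get(gene_of[h], (0.0, 0.0))[1] for h in ids])

    matrices: dict[Arm, CountMatrix] = {}
    for arm, eff in ((Arm.AML, effects_a), (Arm.COUNTER, effects_c)):
        out_abund = input_abund * np.exp2(eff + construct)
        p_in = input_abund / input_abund.sum()
        p_out = out_abund / out_abund.sum()
        cols: dict[str, np.ndarray] = {}
        metas: list[SampleMeta] = []
        total = cfg.depth_per_hairpin * n
        for rep in range(1, cfg.n_replicates + 1):
            for tp, p in ((Timepoint.INPUT, p_in), (Timepoint.OUTPUT, p_out)):
                sid = f"{arm.value}_rep{rep}_{tp.value.lower()}"
                cols[sid] = _nb_draw(rng, total * p, cfg.dispersion)
                metas.append(SampleMeta(sid, arm, rep, tp))
        counts = pd.DataFrame(cols, index=ids)
        matrices[arm] = CountMatrix(counts, metas, library)

    rows = []
    for g in cfg.gene_names:
        ea, ec = cfg.effects.get(g, (0.0, 0.0))
        if ea == 0.0 and ec == 0.0:
            cls = "NEUTRAL"
        elif ec != 0.0:
            cls = "CONFOUNDED"
        elif ea > 0:
            cls = "ENRICHED"
        else:
            cls = "DEPLETED"
        rows.append({"gene": g, "aml_log2_effect": ea, "counter_log2_effect": ec, "class": cls})
    truth = pd.DataFrame(rows)
    return matrices[Arm.AML], matrices[Arm.COUNTER], truth


def simulate_reads(
    cm: CountMatrix,
    library: ShrnaLibrary,
    barcode_map: Mapping[str, str],
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 60,
) -> list[Read]:
    """Emit one barcoded read per count, with optional substitution noise.

    Returns a single deterministically shuffled stream (read = sample
    barcode + guide + random filler); ``write_fastq`` can persist it, or
    per-sample files can be written by grouping on the barcode.  With
    error_rate 0 the demultiplex + count pipeline recovers ``cm`` exactly.
    """
    if not (0.0 <= error_rate <= 0.05):
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    bc_of_sample = {s: b for b, s in barcode_map.items()}
    missing = [c for c in cm.counts.columns if c not in bc_of_sample]
    if missing:
        raise ValueError(f"no barcode for sample(s): {missing}")
    guide_of = {r.hairpin_id: r.guide_seq for r in library.records}
    reads: list[Read] = []
    i = 0
    for sample in cm.counts.columns:
        bc = bc_of_sample[sample]
        for hid, count in cm.counts[sample].items():
            if count == 0:
                continue
            guide = guide_of[hid]
            stem = bc + guide
            fill = read_length - len(stem)
            for _ in range(int(count)):
                if fill > 0:
                    tail = "".join(_NT[rng.integers(0, 4, size=fill)])
                else:
                    tail = ""
                seq = (stem + tail)[:read_length]
                if error_rate > 0:
                    seq = _mutate(rng, seq, error_rate)
                reads.append((f"read{i}:{sample}:{hid}", seq))
                i += 1
    rng.shuffle(reads)
    return reads


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        alt = [c for c in "ACGT" if c != chars[p]]
        chars[p] = alt[rng.integers(0, 3)]
    return "".join(chars)


DEFAULT_COUPLINGS: dict[str, float] = {
    "BIN1_plus12": -1.0,
    "BCL2L1_ratio": -1.0,
    "MYC_signature": -1.0,
}


@dataclass
class CohortSimConfig:
    """Latent-factor model of an AML patient cohort.

    A per-patient latent RBM25 level ~ N(0,1) drives each coupled score
    (coupling in sd units, sign included) plus independent noise, and the
    survival hazard: log-hazard = hazard_log_hr_per_sd * (-RBM25), so a
    negative coupling convention means low RBM25 -> high isoform/MYC
    scores and worse survival.  Baseline survival is exponential with
    median ``baseline_median_months``; censoring thins events uniformly.
    """

    n_patients: int = 180
    rbm25_coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS)
    )
    hazard_log_hr_per_sd: float = 0.7
    censor_rate: float = 0.3
    noise_sd: float = 1.0
    baseline_median_months: float = 18.0
    n_signature_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.rbm25_coupling) - set(DEFAULT_COUPLINGS)
        if unknown:
            raise ValueError(f"unknown coupled score(s): {sorted(unknown)}")


def signature_genes(cfg: CohortSimConfig) -> list[str]:
    return [f"MYC_SIG_{i + 1:02d}" for i in range(cfg.n_signature_genes)]


def simulate_cohort(
    cfg: CohortSimConfig,
) -> tuple[TranscriptMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Returns (transcript matrix, gene matrix, clinical table, truth).

    Transcript-level values are constructed so the cohort scores recover
    the latent values up to a monotone transform: the five exon-12 BIN1
    transcripts split a total of 2^(4 + latent_bin1); the two BCL2L1-L
    transcripts and the single S transcript are balanced around 2^7 so
    the L/S log-ratio equals the latent; signature genes sit at the
    patient's MYC level shifted by the latent MYC activity.
    """
    rng = np.random.default_rng(cfg.seed)
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    rbm25 = rng.normal(0.0, 1.0, cfg.n_patients)

    def latent(name: str) -> np.ndarray:
        coupling = cfg.rbm25_coupling.get(name, 0.0)
        return coupling * rbm25 + rng.normal(0.0, cfg.noise_sd, cfg.n_patients)

    lat_bin1 = latent("BIN1_plus12")
    lat_bcl = latent("BCL2L1_ratio")
    lat_myc = latent("MYC_signature")

    # transcript matrix
    tx_rows: dict[str, np.ndarray] = {}
    bin1_weights = np.array([0.4, 0.25, 0.15, 0.12, 0.08])
    bin1_total = np.exp2(4.0 + lat_bin1)
    for t, w in zip(BIN1_PLUS12.transcript_ids, bin1_weights):
        tx_rows[t] = w * bin1_total
    l_total = np.exp2(7.0 + lat_bcl / 2.0)
    for t, w in zip(BCL2L1_L.transcript_ids, (0.6, 0.4)):
        tx_rows[t] = w * l_total
    tx_rows[BCL2L1_S.transcript_ids[0]] = np.exp2(7.0 - lat_bcl / 2.0)
    tx2gene = {t: "BIN1" for t in BIN1_PLUS12.transcript_ids}
    tx2gene.update({t: "BCL2L1" for t in BCL2L1_L.transcript_ids})
    tx2gene[BCL2L1_S.transcript_ids[0]] = "BCL2L1"
    tm = TranscriptMatrix(pd.DataFrame(tx_rows, index=patients).T, tx2gene)

    # gene matrix: RBM25 tracks the latent; signature genes track MYC * latent activity
    gene_rows: dict[str, np.ndarray] = {"RBM25": np.exp2(8.0 + rbm25)}
    log2_myc = 10.0 + rng.normal(0.0, 0.5, cfg.n_patients)
    gene_rows["MYC"] = np.exp2(log2_myc)
    for g in signature_genes(cfg):
        gene_rows[g] = np.exp2(log2_myc + lat_myc + rng.normal(0.0, 0.3, cfg.n_patients))
    genes = pd.DataFrame(gene_rows, index=patients).T

    # survival: exponential, log-hazard proportional to -RBM25
    rate0 = math.log(2.0) / cfg.baseline_median_months
    rates = rate0 * np.exp(cfg.hazard_log_hr_per_sd * (-rbm25))
    times = rng.exponential(1.0 / rates)
    censored = rng.random(cfg.n_patients) < cfg.censor_rate
    obs_times = np.where(censored, times * rng.uniform(0.0, 1.0, cfg.n_patients), times)
    obs_times = np.maximum(obs_times, 0.01)
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "time_months": np.round(obs_times, 3),
            "event": (~censored).astype(int),
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": patients,
            "rbm25_latent": rbm25,
            "bin1_plus12_latent": lat_bin1,
            "bcl2l1_ratio_latent": lat_bcl,
            "myc_signature_latent": lat_myc,
            "true_time_months": times,
            "censored": censored.astype(int),
        }
    )
    return tm, genes, clinical, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
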