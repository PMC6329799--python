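"""Input/output and read counting for pooled shRNA screens.

A pooled screen is sequenced as barcoded amplicons of the hairpin insert:
each read starts with a 5' sample barcode and contains the guide sequence
of exactly one library hairpin.  This module parses the hairpin library,
demultiplexes reads by barcode, counts guide occurrences per sample and
round-trips count matrices as TSV.

Read assignment is direct guide-sequence search (exact, or within a
Hamming-distance tolerance) inside a configurable offset window, which
replaces external alignment of reads against a hairpin "pseudogenome"
while preserving the same counting contract.  Reads matching two or more
hairpins equally well are discarded as ambiguous rather than fractionally
assigned, so counting is deterministic and conservative.  Hairpins never
observed in a sample are kept as explicit zero rows so that downstream
pseudocounting is uniform.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID_NT = frozenset("ACGT")

#: A sequencing read: (read id, nucleotide sequence).
Read = tuple[str, str]


class Arm(str, enum.Enum):
    """Screen arm: the leukemic screen or the normal-progenitor counter screen."""

    AML = "AML"
    COUNTER = "COUNTER"


class Timepoint(str, enum.Enum):
    INPUT = "INPUT"
    OUTPUT = "OUTPUT"


@dataclass(frozen=True)
class ShrnaRecord:
    """One hairpin of the library.

    ``is_control`` marks scrambled / non-targeting hairpins used as the
    neutral reference for fold-change normalization.
    """

    hairpin_id: str
    gene: str
    guide_seq: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.hairpin_id:
            raise ValueError("hairpin_id must be non-empty")
        if self.guide_seq != self.guide_seq.upper():
            raise ValueError(f"{self.hairpin_id}: guide_seq must be uppercase")
        bad = set(self.guide_seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"{self.hairpin_id}: invalid nucleotide(s) {sorted(bad)} in guide_seq"
            )
        if len(self.guide_seq) < 18:
            raise ValueError(f"{self.hairpin_id}: guide_seq shorter than 18 nt")
        if not self.is_control and not self.gene:
            raise ValueError(f"{self.hairpin_id}: non-control record needs a gene")


@dataclass
class ShrnaLibrary:
    """The screened hairpin collection, optionally partitioned into pools."""

    records: list[ShrnaRecord]
    pools: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        ids = [r.hairpin_id for r in self.records]
        dup_ids = _duplicates(ids)
        if dup_ids:
            raise ValueError(f"duplicate hairpin_id(s): {sorted(dup_ids)}")
        by_guide: dict[str, list[str]] = {}
        for r in self.records:
            by_guide.setdefault(r.guide_seq, []).append(r.hairpin_id)
        dups = {g: hs for g, hs in by_guide.items() if len(hs) > 1}
        if dups:
            offenders = "; ".join(",".join(hs) for hs in dups.values())
            raise ValueError(f"duplicate guide_seq shared by hairpins: {offenders}")
        if self.pools is not None:
            known = set(ids)
            seen: set[str] = set()
            for pool_id, members in self.pools.items():
                unknown = members - known
                if unknown:
                    raise ValueError(f"pool {pool_id}: unknown hairpins {sorted(unknown)}")
                overlap = members & seen
                if overlap:
                    raise ValueError(f"pool {pool_id}: hairpins in two pools {sorted(overlap)}")
                seen |= members

    @property
    def hairpin_ids(self) -> list[str]:
        return [r.hairpin_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.records if not r.is_control})

    @property
    def control_ids(self) -> list[str]:
        return [r.hairpin_id for r in self.records if r.is_control]

    @property
    def guide_map(self) -> dict[str, str]:
        """guide sequence -> hairpin_id"""
        return {r.guide_seq: r.hairpin_id for r in self.records}

    def gene_of(self) -> pd.Series:
        return pd.Series(
            {r.hairpin_id: r.gene for r in self.records}, name="gene", dtype=object
        )

    def is_control_of(self) -> pd.Series:
        return pd.Series(
            {r.hairpin_id: r.is_control for r in self.records}, name="is_control"
        )

    def pool_sizes(self) -> dict[str, int]:
        if not self.pools:
            return {}
        return {p: len(m) for p, m in sorted(self.pools.items())}

    def __len__(self) -> int:
        return len(self.records)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def parse_library(path: str | Path) -> ShrnaLibrary:
    """Read a hairpin library TSV (hairpin_id, gene, guide_seq, is_control).

    Raises ``ValueError`` naming the offending row on duplicate ids/guides
    or invalid nucleotides.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"hairpin_id", "gene", "guide_seq", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        flag_raw = str(row["is_control"]).strip().lower()
        if flag_raw in _TRUTHY:
            flag = True
        elif flag_raw in _FALSY:
            flag = False
        else:
            raise ValueError(f"{path} row {i + 2}: unparseable is_control {flag_raw!r}")
        try:
            records.append(
                ShrnaRecord(
                    hairpin_id=row["hairpin_id"],
                    gene=row["gene"],
                    guide_seq=row["guide_seq"],
                    is_control=flag,
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} row {i + 2}: {e}") from e
    lib = ShrnaLibrary(records)
    log.info(
        "parsed library %s: %d hairpins, %d genes, %d controls",
        path, len(lib), len(lib.genes), len(lib.control_ids),
    )
    return lib


def write_library(lib: ShrnaLibrary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "hairpin_id": [r.hairpin_id for r in lib.records],
            "gene": [r.gene for r in lib.records],
            "guide_seq": [r.guide_seq for r in lib.records],
            "is_control": [int(r.is_control) for r in lib.records],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    arm: Arm
    replicate: int
    timepoint: Timepoint
    barcode: str | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"{self.sample_id}: replicate must be >= 1")
        if self.barcode is not None and (set(self.barcode) - _VALID_NT):
            raise ValueError(f"{self.sample_id}: invalid barcode {self.barcode!r}")


@dataclass
class CountMatrix:
    """Non-negative integer hairpin x sample counts plus sample metadata.

    Rows always cover the full library; hairpins missing from the input
    are restored as explicit zeros (with a warning).
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    library: ShrnaLibrary

    def __post_init__(self) -> None:
        ids = self.library.hairpin_ids
        extra = set(self.counts.index) - set(ids)
        if extra:
            raise ValueError(f"count rows not in library: {sorted(extra)[:5]}")
        missing = set(ids) - set(self.counts.index)
        if missing:
            log.warning("restoring %d missing hairpin row(s) as zeros", len(missing))
            self.counts = self.counts.reindex(ids, fill_value=0)
        else:
            self.counts = self.counts.loc[ids]
        self.counts.index.name = "hairpin_id"
        sample_ids = [s.sample_id for s in self.samples]
        if sorted(sample_ids) != sorted(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in metadata")
        keys = [(s.arm, s.replicate, s.timepoint) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("(arm, replicate, timepoint) must be unique per sample")
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("counts must be finite")
        if (arr < 0).any() or not np.array_equal(arr, np.floor(arr)):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"unknown sample {sample_id!r}")

    def for_arm(self, arm: Arm | str) -> "CountMatrix":
        arm = Arm(arm)
        keep = [s for s in self.samples if s.arm == arm]
        if not keep:
            raise ValueError(f"no samples in arm {arm.value}")
        cols = [s.sample_id for s in keep]
        return CountMatrix(self.counts[cols].copy(), keep, self.library)

    @property
    def replicates(self) -> list[int]:
        return sorted({s.replicate for s in self.samples})


def demultiplex(
    reads: Iterable[Read],
    barcode_map: Mapping[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[Read]], int]:
    """Assign reads to samples by their 5' barcode.

    Returns ``(sample_id -> reads, n_unassigned)``.  A read goes to the
    unique barcode with smallest prefix Hamming distance <= max_mismatch;
    ties or no match within tolerance leave it unassigned.  Barcode sets
    whose pairwise distance is <= 2*max_mismatch are rejected outright
    because ambiguity would then be unavoidable.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    barcodes = list(barcode_map)
    if not barcodes:
        raise ValueError("empty barcode map")
    blen = len(barcodes[0])
    if any(len(b) != blen for b in barcodes):
        raise ValueError("barcodes must share one length")
    for a, b in itertools.combinations(barcodes, 2):
        if _hamming(a, b) <= 2 * max_mismatch:
            raise ValueError(
                f"barcodes {a} and {b} are within 2*max_mismatch; demultiplexing ambiguous"
            )
    out: dict[str, list[Read]] = {s: [] for s in barcode_map.values()}
    unassigned = 0
    for rid, seq in reads:
        prefix = seq[:blen]
        best_d = max_mismatch + 1
        best: list[str] = []
        for bc in barcodes:
            d = _hamming(prefix, bc)
            if d < best_d:
                best_d, best = d, [bc]
            elif d == best_d:
                best.append(bc)
        if len(best) == 1 and best_d <= max_mismatch:
            out[barcode_map[best[0]]].append((rid, seq))
        else:
            unassigned += 1
    log.info(
        "demultiplexed %d reads into %d samples, %d unassigned",
        sum(len(v) for v in out.values()) + unassigned, len(out), unassigned,
    )
    return out, unassigned


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def count_hairpins(
    reads: Iterable[Read],
    library: ShrnaLibrary,
    offset_window: tuple[int, int] | None = None,
    max_mismatch: int = 0,
) -> tuple[pd.Series, int]:
    """Count guide occurrences in a read stream.

    Each read increments at most one hairpin: the one whose guide occurs
    at smallest Hamming distance (<= ``max_mismatch``) at any offset in
    ``offset_window`` (default: the whole read).  Reads matching several
    hairpins equally well count as unmatched.  Returns the per-hairpin
    count vector (zeros included) and the unmatched count.
    """
    if not library.records:
        raise ValueError("empty library")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    guide_map = library.guide_map
    by_len: dict[int, dict[str, str]] = {}
    for g, hid in guide_map.items():
        by_len.setdefault(len(g), {})[g] = hid
    counts: dict[str, int] = {hid: 0 for hid in library.hairpin_ids}
    unmatched = 0
    n_reads = 0
    for _rid, seq in reads:
        n_reads += 1
        lo, hi = (0, len(seq)) if offset_window is None else offset_window
        lo = max(lo, 0)
        # exact fast path: hash every window against the guide dictionary
        exact_hits: set[str] = set()
        for glen, gdict in by_len.items():
            stop = min(hi, len(seq)) - glen
            for o in range(lo, stop + 1):
                hit = gdict.get(seq[o : o + glen])
                if hit is not None:
                    exact_hits.add(hit)
        if len(exact_hits) == 1:
            counts[next(iter(exact_hits))] += 1
            continue
        if len(exact_hits) > 1 or max_mismatch == 0:
            unmatched += 1
            continue
        # mismatch-tolerant scan, early-exit Hamming per window
        best_d = max_mismatch + 1
        best: set[str] = set()
        for guide, hid in guide_map.items():
            glen = len(guide)
            stop = min(hi, len(seq)) - glen
            for o in range(lo, stop + 1):
                seg = seq[o : o + glen]
                d = 0
                for x, y in zip(seg, guide):
                    if x != y:
                        d += 1
                        if d > max_mismatch:
                            break
                if d <= max_mismatch:
                    if d < best_d:
                        best_d, best = d, {hid}
                    elif d == best_d:
                        best.add(hid)
        if len(best) == 1:
            counts[next(iter(best))] += 1
        else:
            unmatched += 1
    if n_reads == 0:
        log.warning("count_hairpins: empty read stream, returning zero vector")
    vec = pd.Series(counts, name="count").reindex(library.hairpin_ids)
    assert int(vec.sum()) + unmatched == n_reads
    return vec.astype(np.int64), unmatched


def library_coverage(cm: CountMatrix, sample: str, min_count: int = 1) -> float:
    """Fraction of library hairpins with count >= min_count in one sample."""
    if sample not in cm.counts.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = cm.counts[sample]
    return float((col >= min_count).mean())


def _samples_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".samples" + path.suffix)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix TSV plus its sample-metadata sidecar TSV."""
    path = Path(path)
    out = cm.counts.copy()
    out.index.name = "hairpin_id"
    out.to_csv(path, sep="\t")
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cm.samples],
            "arm": [s.arm.value for s in cm.samples],
            "replicate": [s.replicate for s in cm.samples],
            "timepoint": [s.timepoint.value for s in cm.samples],
            "barcode": [s.barcode or "" for s in cm.samples],
        }
    ).to_csv(_samples_sidecar(path), sep="\t", index=False)


def read_samples(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                arm=Arm(row["arm"]),
                replicate=int(row["replicate"]),
                timepoint=Timepoint(row["timepoint"]),
                barcode=row.get("barcode") or None,
            )
        )
    return metas


def read_counts(
    path: str | Path,
    library: ShrnaLibrary,
    samples_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count TSV (first column hairpin_id) and its sample sidecar.

    Negative or non-integer cells raise with the offending row/column;
    hairpins of the library missing from the file come back as zeros.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="hairpin_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: invalid count at hairpin {row!r}, sample {col!r}")
    samples = read_samples(samples_path or _samples_sidecar(path))
    return CountMatrix(df, samples, library)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Yield (read_id, sequence) from a FASTQ file; quality is ignored."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as FASTQ with uniform placeholder quality; returns count."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
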