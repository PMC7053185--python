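"""Intratumor methylation-heterogeneity statistics.

Three read-level measures of locally disordered methylation:

* **Epipolymorphism** of a 4-CpG locus: ``1 − Σ pᵢ²`` over the 16 epiallele
  frequencies — a Gini–Simpson diversity, at most 15/16 = 0.9375.
* **Epiallele entropy**: Shannon entropy ``−Σ pᵢ log₂ pᵢ`` in bits (≤ 4),
  also reported normalized to [0, 1] by dividing by 4.
* **PDR** (proportion of discordant reads): among reads carrying at least
  four called CpGs, the fraction containing both methylated and unmethylated
  states, computed per CpG over the eligible reads covering it and averaged
  across CpGs; a CpG contributes only when covered by more than ten eligible
  reads.

Loci are consecutive CpG quartets; entropy/epipolymorphism use only reads
with all four CpGs called and require more than a minimum read count
(default 10) per locus. Undefined metrics propagate as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .epiread_core import MISSING, CpGReference, EpiRead
from .patterns import DISCORDANT, N_CPGS, N_PATTERNS, PATTERN_INDEX, PATTERNS

DEFAULT_MIN_READS = 10
DEFAULT_MIN_CPGS_PER_READ = 4
DEFAULT_MIN_READS_PER_CPG = 11  # "more than ten"
MAX_EPIPOLYMORPHISM = 1.0 - 1.0 / N_PATTERNS


@dataclass(frozen=True)
class Locus:
    """One 4-CpG window: CpG indices ``first_cpg_index .. +3`` on ``contig``."""

    locus_id: str
    contig: str
    first_cpg_index: int

    @property
    def cpg_indices(self) -> tuple[int, int, int, int]:
        i = self.first_cpg_index
        return (i, i + 1, i + 2, i + 3)


@dataclass
class EpialleleLocusTable:
    """Read counts over the 16 patterns at one locus."""

    locus: Locus
    counts: np.ndarray  # length 16, canonical pattern order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_PATTERNS,):
            raise ValueError("counts must have length 16")
        if np.any(self.counts < 0):
            raise ValueError("negative pattern count")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.total_reads

    def count_of(self, pattern: str) -> int:
        return int(self.counts[PATTERN_INDEX[pattern]])


@dataclass(frozen=True)
class LocusMetrics:
    locus_id: str
    contig: str
    first_cpg_index: int
    coverage: int
    entropy_bits: float
    entropy_norm: float
    epipolymorphism: float
    pdr: float  # discordant fraction among this locus's fully-called reads


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample aggregates of the three heterogeneity metrics."""

    sample_id: str
    mean_pdr: float
    mean_entropy: float  # normalized entropy (bits/4)
    mean_entropy_bits: float
    mean_epipolymorphism: float
    n_eligible_loci: int
    n_eligible_cpgs: int


# ---------------------------------------------------------------------------
# Locus enumeration and epiallele counting
# ---------------------------------------------------------------------------

def enumerate_loci(ref: CpGReference, step: int = N_CPGS) -> list[Locus]:
    """Consecutive 4-CpG windows at the given CpG step.

    ``step=4`` (default) gives non-overlapping quartets; ``step=1`` a sliding
    window. Contigs with fewer than 4 CpGs yield no loci.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    loci = []
    for contig in ref.contigs():
        n = ref.n_cpgs(contig)
        for first in range(0, n - N_CPGS + 1, step):
            loci.append(
                Locus(
                    locus_id=f"{contig}:{first}",
                    contig=contig,
                    first_cpg_index=first,
                )
            )
    return loci


def count_epialleles(
    epireads: Iterable[EpiRead],
    loci: Sequence[Locus],
    min_reads: int = DEFAULT_MIN_READS,
) -> list[EpialleleLocusTable]:
    """Tabulate epiallele patterns per locus.

    A read contributes to a locus only when it covers all four of its CpGs
    with called (non-missing) states. Loci accumulating fewer than
    ``min_reads`` contributing reads are dropped.
    """
    starts_by_contig: dict[str, np.ndarray] = {}
    locus_pos: dict[tuple[str, int], int] = {}
    for k, loc in enumerate(loci):
        locus_pos[(loc.contig, loc.first_cpg_index)] = k
    for contig in {loc.contig for loc in loci}:
        starts_by_contig[contig] = np.array(
            sorted(loc.first_cpg_index for loc in loci if loc.contig == contig)
        )

    counts = np.zeros((len(loci), N_PATTERNS), dtype=np.int64)
    for er in epireads:
        starts = starts_by_contig.get(er.contig)
        if starts is None:
            continue
        lo = np.searchsorted(starts, er.first_cpg_index)
        hi = np.searchsorted(starts, er.first_cpg_index + len(er) - N_CPGS, side="right")
        for s in starts[lo:hi]:
            window = er.states[s - er.first_cpg_index : s - er.first_cpg_index + N_CPGS]
            if MISSING in window:
                continue
            k = locus_pos[(er.contig, int(s))]
            counts[k, PATTERN_INDEX[window]] += 1

    out = []
    for k, loc in enumerate(loci):
        if counts[k].sum() >= min_reads:
            out.append(EpialleleLocusTable(locus=loc, counts=counts[k].copy()))
    return out


# ---------------------------------------------------------------------------
# Per-locus metrics
# ---------------------------------------------------------------------------

def epipolymorphism(table: EpialleleLocusTable) -> float:
    """Plug-in epipolymorphism ``1 − Σ pᵢ²``; NaN for an empty table."""
    if table.total_reads == 0:
        return math.nan
    p = table.frequencies
    return float(1.0 - (p**2).sum())


def epiallele_entropy(table: EpialleleLocusTable) -> tuple[float, float]:
    """Plug-in Shannon entropy as ``(bits, normalized)``; NaN when empty."""
    if table.total_reads == 0:
        return math.nan, math.nan
    p = table.frequencies
    nz = p[p > 0]
    bits = float(-(nz * np.log2(nz)).sum())
    return bits, bits / N_CPGS


def locus_discordance(table: EpialleleLocusTable) -> float:
    """Fraction of the locus's reads carrying both an M and a U state."""
    if table.total_reads == 0:
        return math.nan
    return float(table.counts[DISCORDANT].sum() / table.total_reads)


def locus_metrics(table: EpialleleLocusTable) -> LocusMetrics:
    bits, norm = epiallele_entropy(table)
    return LocusMetrics(
        locus_id=table.locus.locus_id,
        contig=table.locus.contig,
        first_cpg_index=table.locus.first_cpg_index,
        coverage=table.total_reads,
        entropy_bits=bits,
        entropy_norm=norm,
        epipolymorphism=epipolymorphism(table),
        pdr=locus_discordance(table),
    )


# ---------------------------------------------------------------------------
# PDR
# ---------------------------------------------------------------------------

@dataclass
class PdrTrack:
    """Per-CpG discordant/eligible read counts and the PDR ratio.

    ``pdr(contig)`` is NaN wherever the eligible-read count is below the
    coverage rule (more than ten reads by default).
    """

    discordant: dict[str, np.ndarray]
    eligible: dict[str, np.ndarray]
    min_reads_per_cpg: int

    def pdr(self, contig: str) -> np.ndarray:
        e = self.eligible[contig]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = self.discordant[contig] / np.maximum(e, 1)
        return np.where(e >= self.min_reads_per_cpg, vals, np.nan)

    def sample_mean(self) -> float:
        """Unweighted mean PDR over CpGs where it is defined; NaN if none."""
        vals = np.concatenate([self.pdr(c) for c in self.discordant]) if self.discordant else np.array([])
        defined = vals[~np.isnan(vals)]
        return float(defined.mean()) if defined.size else math.nan

    def n_defined_cpgs(self) -> int:
        if not self.discordant:
            return 0
        vals = np.concatenate([self.pdr(c) for c in self.discordant])
        return int(np.sum(~np.isnan(vals)))


def pdr(
    epireads: Iterable[EpiRead],
    ref: CpGReference,
    min_cpgs_per_read: int = DEFAULT_MIN_CPGS_PER_READ,
    min_reads_per_cpg: int = DEFAULT_MIN_READS_PER_CPG,
) -> PdrTrack:
    """Proportion of discordant reads per CpG.

    A read is eligible when it carries at least ``min_cpgs_per_read`` called
    states; an eligible read is discordant when its called states contain
    both M and U. Each eligible read contributes to every CpG at which it has
    a called state. PDR at a CpG is defined only when at least
    ``min_reads_per_cpg`` eligible reads cover it.
    """
    discordant = {c: np.zeros(ref.n_cpgs(c), dtype=np.int64) for c in ref.positions}
    eligible = {c: np.zeros(ref.n_cpgs(c), dtype=np.int64) for c in ref.positions}
    for er in epireads:
        if er.n_called < min_cpgs_per_read:
            continue
        disc = er.is_discordant
        e = eligible[er.contig]
        d = discordant[er.contig]
        for j, state in enumerate(er.states):
            if state == MISSING:
                continue
            idx = er.first_cpg_index + j
            e[idx] += 1
            if disc:
                d[idx] += 1
    return PdrTrack(
        discordant=discordant, eligible=eligible, min_reads_per_cpg=min_reads_per_cpg
    )


# ---------------------------------------------------------------------------
# Sample aggregation and output
# ---------------------------------------------------------------------------

def summarize_sample(
    sample_id: str,
    metrics: Sequence[LocusMetrics],
    pdr_track: PdrTrack | None = None,
) -> SampleSummary:
    """Unweighted means of the per-locus metrics and the per-CpG PDR track."""
    ent_norm = [m.entropy_norm for m in metrics if not math.isnan(m.entropy_norm)]
    ent_bits = [m.entropy_bits for m in metrics if not math.isnan(m.entropy_bits)]
    epi = [m.epipolymorphism for m in metrics if not math.isnan(m.epipolymorphism)]
    if pdr_track is not None:
        mean_pdr = pdr_track.sample_mean()
        n_cpgs = pdr_track.n_defined_cpgs()
    else:
        per_locus = [m.pdr for m in metrics if not math.isnan(m.pdr)]
        mean_pdr = float(np.mean(per_locus)) if per_locus else math.nan
        n_cpgs = 0
    return SampleSummary(
        sample_id=sample_id,
        mean_pdr=mean_pdr,
        mean_entropy=float(np.mean(ent_norm)) if ent_norm else math.nan,
        mean_entropy_bits=float(np.mean(ent_bits)) if ent_bits else math.nan,
        mean_epipolymorphism=float(np.mean(epi)) if epi else math.nan,
        n_eligible_loci=len(metrics),
        n_eligible_cpgs=n_cpgs,
    )


def metrics_frame(
    metrics: Sequence[LocusMetrics], ref: CpGReference | None = None
) -> pd.DataFrame:
    """Per-locus metrics as a table, with genomic spans when a ref is given."""
    df = pd.DataFrame(
        {
            "locus_id": [m.locus_id for m in metrics],
            "contig": [m.contig for m in metrics],
            "first_cpg_index": [m.first_cpg_index for m in metrics],
            "coverage": [m.coverage for m in metrics],
            "entropy_bits": [m.entropy_bits for m in metrics],
            "entropy_norm": [m.entropy_norm for m in metrics],
            "epipolymorphism": [m.epipolymorphism for m in metrics],
            "pdr": [m.pdr for m in metrics],
        }
    )
    if ref is not None and len(df):
        starts, ends = [], []
        for m in metrics:
            pos = ref.positions[m.contig]
            starts.append(int(pos[m.first_cpg_index]))
            ends.append(int(pos[m.first_cpg_index + N_CPGS - 1]) + 2)
        df.insert(3, "start", starts)
        df.insert(4, "end", ends)
    return df


def write_metrics_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_loci_bed(df: pd.DataFrame, path) -> None:
    if not {"start", "end"} <= set(df.columns):
        raise ValueError("metrics frame lacks genomic spans; pass ref to metrics_frame")
    df[["contig", "start", "end", "locus_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_summary_tsv(summaries: Sequence[SampleSummary], path) -> None:
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
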