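"""CpG coordinate frame and per-read methylation state extraction.

Everything downstream works in CpG-index space: a :class:`CpGReference` lists
the 0-based position of the C of every forward-strand CpG dinucleotide per
contig, and an :class:`EpiRead` reduces one sequenced fragment to its ordered
methylation calls (``M``/``U``/missing) over a run of consecutive reference
CpGs. Evidence from both strands of a symmetric CpG collapses onto the
forward-strand C.

Coordinates are 0-based half-open throughout; bedGraph output is 0-based.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

MISSING = "."
_STATE_CHARS = frozenset("MU.")

EPIREAD_FORMAT_VERSION = 1
_EPIREAD_HEADER = f"#methylhet_epiread\tv{EPIREAD_FORMAT_VERSION}"


class FormatError(ValueError):
    """Malformed on-disk input (FASTA, epiread TSV, BED)."""


@dataclass(frozen=True)
class CpGReference:
    """Ordered forward-strand CpG positions per contig.

    ``positions[contig]`` is a strictly increasing int array of the 0-based
    positions of the C of each CG dinucleotide; ``contig_lengths`` gives the
    sequence length of each contig.
    """

    positions: Mapping[str, np.ndarray]
    contig_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for contig, pos in self.positions.items():
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"CpG positions not strictly increasing on {contig}")

    def n_cpgs(self, contig: str) -> int:
        return len(self.positions[contig])

    @property
    def total_cpgs(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def contigs(self) -> list[str]:
        return list(self.positions)


@dataclass(frozen=True, slots=True)
class EpiRead:
    """One fragment's ordered CpG methylation calls.

    ``states`` is a string over ``{M, U, .}`` aligned to reference CpG indices
    ``first_cpg_index .. first_cpg_index + len(states) - 1``. Leading and
    trailing states are never missing (trim before constructing).
    """

    read_id: str
    contig: str
    first_cpg_index: int
    states: str

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("empty state string")
        if set(self.states) - _STATE_CHARS:
            raise ValueError(f"invalid state characters in {self.states!r}")
        if self.states[0] == MISSING or self.states[-1] == MISSING:
            raise ValueError("first and last states must not be missing")
        if self.first_cpg_index < 0:
            raise ValueError("negative first_cpg_index")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_called(self) -> int:
        """Number of non-missing methylation calls."""
        return len(self.states) - self.states.count(MISSING)

    @property
    def is_discordant(self) -> bool:
        """True if the called states contain both an M and a U."""
        return "M" in self.states and "U" in self.states


# ---------------------------------------------------------------------------
# CpG index construction
# ---------------------------------------------------------------------------

def _iter_fasta(genome) -> Iterator[tuple[str, str]]:
    if isinstance(genome, dict):
        yield from genome.items()
        return
    if isinstance(genome, (str, os.PathLike)) and not str(genome).lstrip().startswith(">"):
        handle: io.TextIOBase | str = str(genome)
    elif isinstance(genome, str):
        handle = io.StringIO(genome)
    else:
        handle = genome
    for record in SeqIO.parse(handle, "fasta"):
        yield record.id, str(record.seq)


def build_cpg_index(genome) -> CpGReference:
    """Locate every forward-strand CG dinucleotide.

    ``genome`` may be a FASTA path, FASTA text, an open handle, or a mapping
    of contig name to sequence. Case-insensitive; an empty or CpG-free
    sequence yields an empty index for that contig.
    """
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for name, seq in _iter_fasta(genome):
        if name in positions:
            raise FormatError(f"duplicate contig {name!r} in FASTA")
        s = seq.upper()
        positions[name] = np.array(
            [m.start() for m in re.finditer("CG", s)], dtype=np.int64
        )
        lengths[name] = len(s)
    return CpGReference(positions=positions, contig_lengths=lengths)


# ---------------------------------------------------------------------------
# SAM/BAM extraction
# ---------------------------------------------------------------------------

@dataclass
class ExtractionStats:
    """Per-filter record counters from one extraction pass."""

    n_records: int = 0
    n_unmapped: int = 0
    n_secondary_supplementary: int = 0
    n_no_cpg: int = 0
    n_cigar_failures: int = 0
    n_mate_overlap_calls_dropped: int = 0
    n_epireads: int = 0


def _bisulfite_strand(aln) -> str:
    """Decide which strand's conversion chemistry applies to an alignment.

    Honors Bismark's XG tag (CT = original top, GA = original bottom) and
    BSMAP's ZS tag when present; otherwise falls back to the mapping strand.
    """
    if aln.has_tag("XG"):
        return "top" if aln.get_tag("XG") == "CT" else "bottom"
    if aln.has_tag("ZS"):
        return "top" if str(aln.get_tag("ZS")).startswith("+") else "bottom"
    return "bottom" if aln.is_reverse else "top"


def _call_state(base: str, strand: str) -> str:
    if strand == "top":
        return "M" if base == "C" else "U" if base == "T" else MISSING
    return "M" if base == "G" else "U" if base == "A" else MISSING


def extract_epireads(
    alignments,
    ref: CpGReference,
    stats: ExtractionStats | None = None,
) -> list[EpiRead]:
    """Decode per-read CpG methylation states from bisulfite alignments.

    ``alignments`` is a SAM/BAM path or an iterable of pysam records aligned
    to the same genome as ``ref``. At each reference CpG overlapped by the
    aligned portion, the read base is decoded as M/U by the strand convention
    (top: C→M, T→U; bottom, at the G of the CpG: G→M, A→U); anything else,
    including a deletion, is a missing call. Reads overlapping no CpG are
    dropped. Where paired mates overlap, the first mate's calls win.
    """
    import pysam

    if stats is None:
        stats = ExtractionStats()
    close = None
    if isinstance(alignments, (str, os.PathLike)):
        afile = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable = afile
        close = afile
    else:
        records = alignments

    seen_mate_calls: dict[str, set[tuple[str, int]]] = {}
    out: list[EpiRead] = []
    try:
        for aln in records:
            stats.n_records += 1
            if aln.is_unmapped:
                stats.n_unmapped += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                stats.n_secondary_supplementary += 1
                continue
            contig = aln.reference_name
            if contig not in ref.positions:
                stats.n_no_cpg += 1
                continue
            try:
                pairs = aln.get_aligned_pairs(matches_only=False)
            except Exception:
                stats.n_cigar_failures += 1
                continue
            cpg_pos = ref.positions[contig]
            lo = np.searchsorted(cpg_pos, aln.reference_start)
            hi = np.searchsorted(cpg_pos, aln.reference_end)
            strand = _bisulfite_strand(aln)
            if strand == "bottom":
                # the informative base sits on the G of the CpG
                lo = np.searchsorted(cpg_pos + 1, aln.reference_start)
                hi = np.searchsorted(cpg_pos + 1, aln.reference_end)
            if hi <= lo:
                stats.n_no_cpg += 1
                continue

            ref_to_query = {
                rpos: qpos for qpos, rpos in pairs if rpos is not None
            }
            seq = aln.query_sequence or ""
            states = []
            for idx in range(lo, hi):
                target = int(cpg_pos[idx]) + (1 if strand == "bottom" else 0)
                qpos = ref_to_query.get(target)
                if qpos is None or qpos >= len(seq):
                    states.append(MISSING)
                else:
                    states.append(_call_state(seq[qpos].upper(), strand))

            if aln.is_paired:
                key = aln.query_name
                called = seen_mate_calls.setdefault(key, set())
                for j, idx in enumerate(range(lo, hi)):
                    tag = (contig, idx)
                    if states[j] == MISSING:
                        continue
                    if tag in called:
                        states[j] = MISSING
                        stats.n_mate_overlap_calls_dropped += 1
                    else:
                        called.add(tag)

            epiread = _trim_to_epiread(aln.query_name, contig, int(lo), states)
            if epiread is None:
                stats.n_no_cpg += 1
                continue
            out.append(epiread)
            stats.n_epireads += 1
    finally:
        if close is not None:
            close.close()
    return out


def _trim_to_epiread(
    read_id: str, contig: str, first_index: int, states: list[str]
) -> EpiRead | None:
    """Trim leading/trailing missing calls; None if nothing was called."""
    s = "".join(states)
    stripped = s.strip(MISSING)
    if not stripped:
        return None
    offset = len(s) - len(s.lstrip(MISSING))
    return EpiRead(
        read_id=read_id,
        contig=contig,
        first_cpg_index=first_index + offset,
        states=stripped,
    )


# ---------------------------------------------------------------------------
# Beta track
# ---------------------------------------------------------------------------

@dataclass
class BetaTrack:
    """Per-CpG methylated and total call counts; beta = methylated/total.

    Beta is NaN (undefined, never 0) at CpGs with no calls.
    """

    meth: dict[str, np.ndarray]
    total: dict[str, np.ndarray]

    def beta(self, contig: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.total[contig] > 0,
                self.meth[contig] / np.maximum(self.total[contig], 1),
                np.nan,
            )

    def contigs(self) -> list[str]:
        return list(self.meth)


def compute_beta_track(epireads: Iterable[EpiRead], ref: CpGReference) -> BetaTrack:
    """Accumulate per-CpG methylation counts from epireads (missing excluded)."""
    meth = {c: np.zeros(ref.n_cpgs(c), dtype=np.int64) for c in ref.positions}
    total = {c: np.zeros(ref.n_cpgs(c), dtype=np.int64) for c in ref.positions}
    for er in epireads:
        m = meth[er.contig]
        t = total[er.contig]
        for j, state in enumerate(er.states):
            if state == MISSING:
                continue
            idx = er.first_cpg_index + j
            t[idx] += 1
            if state == "M":
                m[idx] += 1
    return BetaTrack(meth=meth, total=total)


# ---------------------------------------------------------------------------
# Epiread TSV dialect
# ---------------------------------------------------------------------------

def write_epiread_tsv(epireads: Iterable[EpiRead], path) -> int:
    """Write the tab-separated epiread dialect; returns the number of reads."""
    n = 0
    with open(path, "w") as fh:
        fh.write(_EPIREAD_HEADER + "\n")
        for er in epireads:
            fh.write(f"{er.contig}\t{er.first_cpg_index}\t{er.read_id}\t{er.states}\n")
            n += 1
    return n


def read_epiread_tsv(path) -> list[EpiRead]:
    """Read the epiread dialect; raises :class:`FormatError` with line numbers."""
    out: list[EpiRead] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#methylhet_epiread"):
            raise FormatError(f"{path}: missing epiread header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            contig, first_idx, read_id, states = fields
            if set(states) - _STATE_CHARS:
                bad = sorted(set(states) - _STATE_CHARS)
                raise FormatError(
                    f"{path}:{lineno}: invalid state character(s) {bad} in {states!r}"
                )
            try:
                out.append(
                    EpiRead(
                        read_id=read_id,
                        contig=contig,
                        first_cpg_index=int(first_idx),
                        states=states,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_betas_bedgraph(track: BetaTrack, ref: CpGReference, path) -> None:
    """Write per-CpG betas as bedGraph (0-based single-base intervals)."""
    with open(path, "w") as fh:
        for contig in track.contigs():
            beta = track.beta(contig)
            pos = ref.positions[contig]
            for p, b in zip(pos, beta):
                if np.isnan(b):
                    continue
                fh.write(f"{contig}\t{p}\t{p + 1}\t{b:.6g}\n")
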