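"""Synthetic bisulfite-read cohorts with known epiallele structure.

The generator emulates paired tumor/normal-style WGBS cohorts at the level of
4-CpG epiallele loci. Each locus carries a ground-truth distribution over the
16 methylation patterns built from a clonal mixture: a concordant founder
epiallele (fully methylated or fully unmethylated) plus derived clones that
arose by stochastic epimutation of the founder, mixed with Dirichlet weights.
Reads are whole-locus observations of a pattern draw, with independent
per-CpG state flips modelling bisulfite conversion error and locally
disordered methylation.

Because every locus has a closed-form pattern distribution, every
heterogeneity metric (entropy, epipolymorphism, discordant-read proportion)
has an exact expected value, computable by :func:`expected_metrics` — the
analytic oracle used throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .epiread_core import CpGReference, EpiRead
from .patterns import (
    DISCORDANT,
    N_CPGS,
    N_PATTERNS,
    PATTERN_INDEX,
    PATTERNS,
    perturb,
)


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Configuration and ground-truth objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpialleleDistribution:
    """Ground-truth pattern distribution of one 4-CpG locus."""

    locus_id: str
    pattern_probs: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.pattern_probs)
        if keys != set(PATTERNS):
            raise ConfigurationError(
                f"pattern_probs must have exactly the 16 four-CpG patterns; "
                f"got {len(keys)} keys"
            )
        vec = self.probs
        if np.any(vec < 0):
            raise ConfigurationError("negative pattern probability")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"probabilities sum to {vec.sum()}, not 1")

    @property
    def probs(self) -> np.ndarray:
        """Probability vector ordered by the canonical pattern index."""
        return np.array([self.pattern_probs[p] for p in PATTERNS], dtype=float)

    @classmethod
    def from_sparse(cls, locus_id: str, probs: Mapping[str, float]) -> "EpialleleDistribution":
        """Build from a partial mapping; unlisted patterns get probability 0."""
        full = {p: 0.0 for p in PATTERNS}
        for k, v in probs.items():
            if k not in full:
                raise ConfigurationError(f"unknown pattern {k!r}")
            full[k] = float(v)
        return cls(locus_id=locus_id, pattern_probs=full)

    @classmethod
    def from_vector(cls, locus_id: str, vec: np.ndarray) -> "EpialleleDistribution":
        return cls(locus_id=locus_id, pattern_probs=dict(zip(PATTERNS, map(float, vec))))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated methylome.

    coverage follows a negative binomial with mean ``coverage_mean`` and
    dispersion ``coverage_dispersion`` (Poisson in the dispersion→∞ limit);
    ``error_rate`` is the per-CpG state-flip probability; ``clonality`` the
    number of clone epialleles per locus and ``clone_mix_alpha`` the symmetric
    Dirichlet concentration of their mixing proportions. ``founder_meth_prob``
    is the chance the founder clone is fully methylated (vs fully
    unmethylated) and ``clone_divergence`` the per-CpG epimutation rate of
    derived clones relative to the founder.
    """

    n_loci: int = 100
    cpg_spacing: int = 30
    locus_spacing: int = 300
    coverage_mean: float = 25.0
    coverage_dispersion: float = 5.0
    error_rate: float = 0.01
    clonality: int = 2
    clone_mix_alpha: float = 1.0
    founder_meth_prob: float = 0.7
    clone_divergence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be > 0")
        if self.coverage_dispersion <= 0:
            raise ConfigurationError("coverage_dispersion must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ConfigurationError("error_rate must lie in [0, 0.5)")
        if not (1 <= self.clonality <= 16):
            raise ConfigurationError("clonality must lie in [1, 16]")
        if self.clone_mix_alpha <= 0:
            raise ConfigurationError("clone_mix_alpha must be > 0")
        if self.cpg_spacing < 2:
            raise ConfigurationError("cpg_spacing must be >= 2")
        if self.locus_spacing < 2:
            raise ConfigurationError("locus_spacing must be >= 2")
        if not (0.0 <= self.founder_meth_prob <= 1.0):
            raise ConfigurationError("founder_meth_prob must lie in [0, 1]")
        if not (0.0 <= self.clone_divergence <= 1.0):
            raise ConfigurationError("clone_divergence must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with a heterogeneity shift and linked survival.

    The high-heterogeneity group receives ``group_effect`` as an additive
    shift on ``group_effect_target`` (the per-CpG disorder rate by default,
    which moves PDR, entropy and epipolymorphism jointly; alternatively the
    clone-mixing concentration). Survival times are exponential with hazard
    ``survival_baseline_hazard * exp(survival_log_hazard_per_unit_het * h)``
    where ``h`` is the sample's mean expected epipolymorphism; censoring is an
    independent exponential at ``censoring_rate`` (0 disables censoring).
    """

    n_per_group: int = 20
    group_effect: float = 0.05
    group_effect_target: str = "error_rate"  # or "clone_mix_alpha"
    survival_baseline_hazard: float = 0.05
    survival_log_hazard_per_unit_het: float = 2.0
    censoring_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.survival_baseline_hazard <= 0:
            raise ConfigurationError("survival_baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ConfigurationError("censoring_rate must be >= 0")
        if self.group_effect_target not in ("error_rate", "clone_mix_alpha"):
            raise ConfigurationError(
                "group_effect_target must be 'error_rate' or 'clone_mix_alpha'"
            )


@dataclass(frozen=True)
class ExpectedMetrics:
    """Closed-form locus metrics on the error-perturbed pattern distribution."""

    entropy_bits: float
    entropy_norm: float
    epipolymorphism: float
    pdr: float


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

_FILLER = np.array(list("ACT"))  # no G: CpGs occur only where placed


def simulate_reference(
    config: SimulationConfig, contig: str = "chrS"
) -> tuple[CpGReference, dict[str, str]]:
    """Synthesize a contig whose CpGs sit exactly at the generated loci.

    Lays down ``n_loci`` groups of 4 CpG dinucleotides, CpGs within a locus
    separated by ~``cpg_spacing`` bp and loci by ``locus_spacing`` bp. The
    filler alphabet contains no G, so CG dinucleotides occur nowhere else.
    """
    rng = np.random.default_rng(config.seed)
    positions: list[int] = []
    cursor = config.locus_spacing
    for _ in range(config.n_loci):
        for j in range(N_CPGS):
            positions.append(cursor)
            gap = max(2, int(rng.poisson(config.cpg_spacing)))
            cursor += gap
        cursor += config.locus_spacing
    length = cursor + config.locus_spacing
    seq = rng.choice(_FILLER, size=length)
    for p in positions:
        seq[p] = "C"
        seq[p + 1] = "G"
    sequence = "".join(seq)
    ref = CpGReference(
        positions={contig: np.array(positions, dtype=np.int64)},
        contig_lengths={contig: length},
    )
    return ref, {contig: sequence}


# ---------------------------------------------------------------------------
# Ground-truth distributions: clonal mixture model
# ---------------------------------------------------------------------------

_DISCORDANT_IDX = np.flatnonzero(DISCORDANT)
_POPCOUNT = np.array([bin(i).count("1") for i in range(N_PATTERNS)])


def clonal_distributions(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    locus_ids: Sequence[str] | None = None,
) -> list[EpialleleDistribution]:
    """Draw one clonal-mixture pattern distribution per locus.

    The founder clone is a concordant epiallele (MMMM with probability
    ``founder_meth_prob``, else UUUU) and receives the largest of the
    symmetric Dirichlet(``clone_mix_alpha``) mixing weights — the founding
    clone dominates the locus. The remaining ``clonality − 1`` clones are
    distinct epimutated subclones: partially methylated (discordant)
    epialleles sampled without replacement, weighted by
    ``clone_divergence^h (1 − clone_divergence)^(4−h)`` where ``h`` is the
    number of CpGs mutated away from the founder (``clone_divergence = 0.5``
    makes all 14 discordant epialleles equally likely). With one clone the
    locus is perfectly homogeneous; each extra clone adds discordant mass,
    so entropy, epipolymorphism and the expected discordant-read proportion
    all rise together with clonality.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = []
    n_derived = config.clonality - 1
    for i in range(config.n_loci):
        vec = np.zeros(N_PATTERNS)
        founder_idx = (
            N_PATTERNS - 1 if rng.random() < config.founder_meth_prob else 0
        )
        weights = np.sort(rng.dirichlet([config.clone_mix_alpha] * config.clonality))[::-1]
        vec[founder_idx] += weights[0]
        if n_derived:
            h = np.where(
                founder_idx == 0,
                _POPCOUNT[_DISCORDANT_IDX],
                N_CPGS - _POPCOUNT[_DISCORDANT_IDX],
            )
            d = np.clip(config.clone_divergence, 1e-12, 1 - 1e-12)
            p = d**h * (1.0 - d) ** (N_CPGS - h)
            p = p / p.sum()
            k = min(n_derived, len(_DISCORDANT_IDX))
            derived = list(rng.choice(_DISCORDANT_IDX, size=k, replace=False, p=p))
            if n_derived > k:
                derived += list(
                    rng.choice(_DISCORDANT_IDX, size=n_derived - k, replace=True, p=p)
                )
            for w, idx in zip(weights[1:], derived):
                vec[idx] += w
        locus_id = locus_ids[i] if locus_ids is not None else f"locus{i:05d}"
        out.append(EpialleleDistribution.from_vector(locus_id, vec))
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _draw_coverage(config: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    r = config.coverage_dispersion
    p = r / (r + config.coverage_mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_epireads(
    config: SimulationConfig,
    distributions: Sequence[EpialleleDistribution],
    rng: np.random.Generator | None = None,
    contig: str = "chrS",
    coverage: int | None = None,
    partial_fraction: float = 0.0,
) -> list[EpiRead]:
    """Simulate whole-locus reads for one sample.

    Locus ``i`` occupies CpG indices ``4i .. 4i+3``. Per locus the read count
    is negative binomial (or the fixed ``coverage`` when given); each read's
    pattern is drawn from the locus distribution and then each state flips
    independently with ``error_rate``. With ``partial_fraction > 0`` that
    fraction of reads loses a uniform prefix or suffix of states (at least
    one state survives), exercising missing-data handling downstream.
    """
    if len(distributions) != config.n_loci:
        raise ConfigurationError(
            f"{len(distributions)} distributions for {config.n_loci} loci"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reads: list[EpiRead] = []
    counts = (
        np.full(config.n_loci, coverage, dtype=np.int64)
        if coverage is not None
        else _draw_coverage(config, rng, config.n_loci)
    )
    for i, dist in enumerate(distributions):
        n = int(counts[i])
        if n == 0:
            continue
        pattern_idx = rng.choice(N_PATTERNS, size=n, p=dist.probs)
        bits = (pattern_idx[:, None] >> np.arange(N_CPGS - 1, -1, -1)) & 1
        if config.error_rate > 0:
            flips = rng.random((n, N_CPGS)) < config.error_rate
            bits = bits ^ flips
        for j in range(n):
            states = "".join("M" if b else "U" for b in bits[j])
            first = N_CPGS * i
            if partial_fraction > 0 and rng.random() < partial_fraction:
                keep = int(rng.integers(1, N_CPGS))  # surviving length
                if rng.random() < 0.5:
                    states = states[:keep]
                else:
                    states = states[-keep:]
                    first += N_CPGS - keep
            reads.append(
                EpiRead(
                    read_id=f"L{i:05d}_R{j:04d}",
                    contig=contig,
                    first_cpg_index=first,
                    states=states,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

def expected_metrics(
    dist: EpialleleDistribution, error_rate: float = 0.0
) -> ExpectedMetrics:
    """Exact metric values on the error-perturbed pattern distribution.

    The perturbed distribution is computed by summing over all flip events
    (a 16x16 transition matrix). Entropy is Shannon entropy in bits,
    epipolymorphism is 1 − Σp'², and the expected discordant-read proportion
    is the total perturbed mass on patterns carrying both an M and a U.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ConfigurationError("error_rate must lie in [0, 0.5)")
    p = perturb(dist.probs, error_rate)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    epipoly = float(1.0 - (p**2).sum())
    pdr = float(p[DISCORDANT].sum())
    return ExpectedMetrics(
        entropy_bits=entropy,
        entropy_norm=entropy / N_CPGS,
        epipolymorphism=epipoly,
        pdr=pdr,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    config: SimulationConfig
    distributions: list[EpialleleDistribution]
    epireads: list[EpiRead]
    mean_expected_epipolymorphism: float
    time: float
    event: int


@dataclass
class SimulatedCohort:
    samples: list[SimulatedSample]
    spec: CohortSpec
    config: SimulationConfig

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "time": [s.time for s in self.samples],
                "event": [s.event for s in self.samples],
            }
        )


def _group_config(config: SimulationConfig, spec: CohortSpec, high: bool) -> SimulationConfig:
    if not high or spec.group_effect == 0:
        return config
    if spec.group_effect_target == "error_rate":
        return replace(config, error_rate=config.error_rate + spec.group_effect)
    return replace(config, clone_mix_alpha=config.clone_mix_alpha + spec.group_effect)


def sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    """Deterministic child generator for one sample of a cohort."""
    return np.random.default_rng(np.random.SeedSequence((seed, sample_index)))


def simulate_cohort(spec: CohortSpec, config: SimulationConfig) -> SimulatedCohort:
    """Generate a two-group cohort with heterogeneity-linked survival.

    Groups are labelled ``low`` and ``high``; the high group's generating
    configuration receives the heterogeneity shift. Each sample gets its own
    clonal distributions and reads from a per-sample child seed, so cohorts
    are reproducible read-for-read given (seed, config, spec).
    """
    samples: list[SimulatedSample] = []
    idx = 0
    for group, high in (("low", False), ("high", True)):
        gconfig = _group_config(config, spec, high)
        for _ in range(spec.n_per_group):
            rng = sample_rng(config.seed, idx)
            dists = clonal_distributions(gconfig, rng)
            reads = simulate_epireads(gconfig, dists, rng)
            mean_epi = float(
                np.mean(
                    [expected_metrics(d, gconfig.error_rate).epipolymorphism for d in dists]
                )
            )
            hazard = spec.survival_baseline_hazard * np.exp(
                spec.survival_log_hazard_per_unit_het * mean_epi
            )
            t_event = rng.exponential(1.0 / hazard)
            if spec.censoring_rate > 0:
                t_cens = rng.exponential(1.0 / spec.censoring_rate)
                time, event = (min(t_event, t_cens), int(t_event <= t_cens))
            else:
                time, event = t_event, 1
            samples.append(
                SimulatedSample(
                    sample_id=f"S{idx:03d}",
                    group=group,
                    config=gconfig,
                    distributions=dists,
                    epireads=reads,
                    mean_expected_epipolymorphism=mean_epi,
                    time=float(time),
                    event=event,
                )
            )
            idx += 1
    return SimulatedCohort(samples=samples, spec=spec, config=config)


# ---------------------------------------------------------------------------
# On-disk outputs
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_ground_truth_tsv(
    distributions: Sequence[EpialleleDistribution], error_rate: float, path
) -> None:
    rows = []
    for d in distributions:
        em = expected_metrics(d, error_rate)
        rows.append(
            {
                "locus_id": d.locus_id,
                "expected_entropy": em.entropy_bits,
                "expected_epipolymorphism": em.epipolymorphism,
                "expected_pdr": em.pdr,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def bisulfite_read_sequence(
    sequence: str, ref: CpGReference, contig: str, epiread: EpiRead, margin: int = 5
) -> tuple[int, str]:
    """Top-strand bisulfite-converted read sequence realizing an epiread.

    Returns (0-based alignment start, read sequence). Non-CpG cytosines are
    fully converted to T; each covered CpG's C reads as C (methylated) or T.
    """
    pos = ref.positions[contig]
    first = int(pos[epiread.first_cpg_index])
    last = int(pos[epiread.first_cpg_index + len(epiread) - 1])
    start = max(0, first - margin)
    end = min(len(sequence), last + 2 + margin)
    bases = list(sequence[start:end].upper())
    cpg_here = {
        int(pos[epiread.first_cpg_index + j]): st
        for j, st in enumerate(epiread.states)
    }
    for i, b in enumerate(bases):
        gpos = start + i
        if gpos in cpg_here:
            st = cpg_here[gpos]
            bases[i] = "C" if st == "M" else "T" if st == "U" else "N"
        elif b == "C":
            bases[i] = "T"
    return start, "".join(bases)


def write_sam(
    epireads: Iterable[EpiRead],
    ref: CpGReference,
    sequences: Mapping[str, str],
    path,
) -> None:
    """Write a minimal coordinate-style SAM of top-strand converted reads."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig, length in ref.contig_lengths.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for er in epireads:
            start, seq = bisulfite_read_sequence(
                sequences[er.contig], ref, er.contig, er
            )
            fh.write(
                f"{er.read_id}\t0\t{er.contig}\t{start + 1}\t60\t{len(seq)}M\t*\t0\t0\t"
                f"{seq}\t*\tXG:Z:CT\n"
            )
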