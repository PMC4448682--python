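"""Domain types shared across the pipeline.

Coordinates are 0-based, half-open, genomic, and carry an explicit strand.
All intervals are ``(start, end)`` tuples with ``start < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Interval = tuple[int, int]

EVENT_CLASSES = ("SE", "A5SS", "A3SS", "RI", "MXE", "TandemUTR", "ALE")


@dataclass(frozen=True)
class SpliceEvent:
    """An annotated alternative event.

    ``intervals`` maps role names to genomic intervals. Roles by class:

    * ``SE`` — ``exon``, ``upstream_intron``, ``downstream_intron``
    * ``TandemUTR`` — ``core`` (shared by both isoforms), ``extension``
      (present only in the distal-PAS isoform)
    * ``ALE`` — ``ale1``, ``ale2`` (mutually exclusive last exons)
    """

    event_id: str
    event_class: str
    gene_id: str
    chrom: str
    strand: str
    intervals: dict[str, Interval]

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, (s, e) in self.intervals.items():
            if e <= s:
                raise ValueError(f"empty interval {name} in {self.event_id}")

    @property
    def exon_length(self) -> int:
        """Length of the alternative exon (SE events)."""
        s, e = self.intervals["exon"]
        return e - s


@dataclass(frozen=True)
class PsiEstimate:
    """Posterior summary of percent-spliced-in for one event in one sample."""

    event_id: str
    sample_id: str
    inclusion_count: int
    exclusion_count: int
    psi_mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.inclusion_count < 0 or self.exclusion_count < 0:
            raise ValueError("read counts must be non-negative")
        if not (self.ci_low <= self.psi_mean <= self.ci_high):
            raise ValueError("credible interval must contain the posterior mean")


@dataclass(frozen=True)
class PairwiseComparison:
    """Posterior change in PSI between two samples with a Bayes factor.

    ``delta_psi`` is oriented sample_b minus sample_a.
    """

    event_id: str
    sample_a: str
    sample_b: str
    delta_psi: float
    bayes_factor: float
    bf_capped: bool = False


@dataclass(frozen=True)
class MonotonicityResult:
    event_id: str
    delta: int
    null_mean: float
    null_sd: float
    mz: float
    n_perm: int
    flag: str = ""

    @property
    def degenerate(self) -> bool:
        return self.flag == "degenerate_null"


@dataclass(frozen=True)
class ClipRead:
    """A mapped crosslinking read.

    ``substitutions`` holds ``(offset, ref_base, read_base)`` records with the
    offset relative to ``start`` on the plus strand of the genome.
    """

    chrom: str
    start: int
    end: int
    strand: str
    read_id: str
    substitutions: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        for off, ref, alt in self.substitutions:
            if not (0 <= off < self.end - self.start):
                raise ValueError(f"substitution offset {off} outside read {self.read_id}")
            if ref not in "ACGT" or alt not in "ACGT":
                raise ValueError(f"bases must be ACGT in read {self.read_id}")


@dataclass(frozen=True)
class ClipCluster:
    chrom: str
    start: int
    end: int
    strand: str
    read_count: int
    max_height: int


@dataclass(frozen=True)
class BindingSite:
    """A point binding location for one protein inside a 3' UTR."""

    protein: str
    gene_id: str
    position: int
    source: str  # "motif_in_cluster" or "cluster_center"


@dataclass
class UtrBindingProfile:
    gene_id: str
    n_core_clusters: int = 0
    n_extension_clusters: int = 0
    n_ale1_clusters: int = 0
    n_ale2_clusters: int = 0
    cluster_density_per_kb: float = 0.0
    psi_extension: Optional[float] = None
    psi_ale1: Optional[float] = None
    psi_ale2: Optional[float] = None


@dataclass(frozen=True)
class PotencyFit:
    """Per-site effect estimates from the log-linear expression model."""

    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    percent_per_site: dict[str, float]
    percent_ci: dict[str, tuple[float, float]]
    n_genes: int
    residual_sd: float


@dataclass
class RbnsExperiment:
    """Kmer count tables for an input/pulldown library pair."""

    condition: str
    input_counts: dict[str, int]
    pulldown_counts: dict[str, int]
    read_length: int = 40
    k: int = 6
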