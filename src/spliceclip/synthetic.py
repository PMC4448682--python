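"""Synthetic data generation with known ground truth.

Every input the pipeline consumes can be generated here: an annotated
synthetic genome with cassette-exon and alternative 3' UTR events,
time-course inclusion/exclusion and gene read counts, CLIP reads with
planted crosslink-induced substitutions, and RNA Bind-n-Seq libraries drawn
under a kmer-affinity model.  All generators are fully deterministic under a
fixed seed.

The defaults emulate the study design the analyses assume: three replicate
samples at each of a control point and four post-induction time points
(0h, 12h, 24h, 72h, 7d); CELF binding sites are UGU-containing motifs whose
central guanine crosslinks with probability 0.3; expression changes follow
the log-linear potency model with per-site percent effects of 6.9 (tandem
core), 2.7 (tandem extension) and 5.9 (ALE); exonic CELF binding represses
the bound cassette exon in ~82.5% of regulated cases; CELF/MBNL co-binding
is planted at threefold the independence expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import ClipRead, SpliceEvent
from .utr import percent_to_coef

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_TIMEPOINTS = ("0h", "12h", "24h", "72h", "7d")

def default_celf_affinities(k: int = 6) -> dict[str, float]:
    """Graded CELF1 kmer affinity spectrum for the RBNS generator.

    Affinity grows with UGU and GU content — a continuum over GU-rich kmers
    rather than a handful of spikes, with UGUUGU as the strongest binder —
    emulating the broad single-protein enrichment profile of GU-binding
    proteins in this assay.  Weights are per-occurrence contributions to a
    read's pulldown sampling weight.
    """
    from itertools import product as _product

    out: dict[str, float] = {}
    for tup in _product("ACGU", repeat=k):
        km = "".join(tup)
        n_ugu = sum(1 for i in range(k - 2) if km[i:i + 3] == "UGU")
        n_gu = sum(1 for i in range(k - 1) if km[i:i + 2] == "GU")
        a = 1.5 * n_ugu + 0.25 * n_gu
        if a > 0:
            out[km] = a
    out["UGUUGU"] += 2.0
    return out


#: CELF1 RBNS affinity model: enrichment weight per kmer occurrence
DEFAULT_CELF_AFFINITIES = default_celf_affinities()

CELF_PLANT_MOTIF = "TGTT"   # contains the UGU crosslink context at offset 0-2
MBNL_PLANT_MOTIF = "GCTT"   # GCU context


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Knobs for all generators; the defaults are the emulated study design."""

    n_genes: int = 60
    n_timepoints: int = 5
    n_replicates: int = 3
    read_depth: int = 200            # reads per splicing event per sample
    frac_monotone: float = 0.5
    frac_tandem: float = 0.5         # remainder of UTR events are ALE pairs
    # per-site log-scale potency coefficients (positive = repression)
    potency_core: float = -percent_to_coef(6.9)
    potency_extension: float = -percent_to_coef(2.7)
    potency_ale: float = -percent_to_coef(5.9)
    noise_sd: float = 0.2            # gene-level log-expression noise
    count_noise_sd: float = 0.05     # per-sample lognormal measurement noise
    base_log_expression: float = float(np.log(1000.0))
    # cassette-exon regulation
    exonic_repression_rate: float = 0.825
    exonic_bound_fraction: float = 0.5
    # UTR isoform regulation
    proximal_shift_rate: float = 0.75
    # CLIP read generation
    clip_reads: int = 4000
    clip_read_length: int = 30
    background_fraction: float = 0.2
    substitution_prob: float = 0.3
    background_substitution_prob: float = 0.01
    duplicate_rate: float = 0.1
    # co-binding
    p_celf_target: float = 0.25
    p_mbnl_target: float = 0.25
    cobind_factor: float = 3.0
    proximal_pair_fraction: float = 0.5
    proximal_window: int = 30
    min_sites: int = 2
    max_sites: int = 4
    # geometry (nt)
    exon1_len: int = 100
    intron_len: int = 150
    last_pre_len: int = 100
    core_len: int = 300
    extension_len: int = 300
    ale_len: int = 300
    ale_spacer: int = 100
    gene_gap: int = 100
    minus_strand_fraction: float = 0.5
    seed: int = 0
    timepoint_labels: tuple[str, ...] = DEFAULT_TIMEPOINTS

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2 (need a control/target contrast)")
        for name in ("n_timepoints", "n_replicates", "read_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_monotone", "frac_tandem", "background_fraction",
                     "duplicate_rate", "substitution_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    utr_type: str                      # "tandem" or "ale"
    regions: dict[str, tuple[int, int]]       # genomic intervals
    sense_offsets: dict[str, tuple[int, int]]  # sense-coordinate intervals

    def genomic_pos(self, region: str, offset: int) -> int:
        """Genomic position of a sense offset within a named region."""
        gs, ge = self.regions[region]
        if self.strand == "+":
            return gs + offset
        return ge - 1 - offset

    def sense_pos(self, genomic_pos: int) -> int:
        """Sense-coordinate position (0 at the gene's 5' end) of a genomic
        position inside the gene."""
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - 1 - genomic_pos

    def utr_offset(self, genomic_pos: int) -> int:
        """Offset within the 3' UTR (0 at the UTR's 5' boundary)."""
        first = "core" if self.utr_type == "tandem" else "ale1"
        return self.sense_pos(genomic_pos) - self.sense_offsets[first][0]

    @property
    def utr_length(self) -> int:
        if self.utr_type == "tandem":
            return (self.regions["core"][1] - self.regions["core"][0]
                    + self.regions["extension"][1] - self.regions["extension"][0])
        return (self.regions["ale1"][1] - self.regions["ale1"][0]
                + self.regions["ale2"][1] - self.regions["ale2"][0])


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for parameter recovery."""

    psi_trajectories: dict[str, np.ndarray] = field(default_factory=dict)
    trajectory_labels: dict[str, str] = field(default_factory=dict)
    log_expression_change: dict[str, float] = field(default_factory=dict)
    celf_sites: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    mbnl_sites: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    crosslink_positions: dict[str, list[int]] = field(default_factory=dict)
    celf_targets: set[str] = field(default_factory=set)
    mbnl_targets: set[str] = field(default_factory=set)
    rbns_affinities: dict[str, float] = field(default_factory=dict)

    def site_count(self, gene_id: str, region: str, protein: str = "CELF1") -> int:
        table = self.celf_sites if protein == "CELF1" else self.mbnl_sites
        return len(table.get(gene_id, {}).get(region, []))


@dataclass
class Annotation:
    genome: dict[str, str]
    genes: list[GeneModel]
    events: list[SpliceEvent]
    truth: SyntheticTruth
    config: SimulationConfig

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _plant_motifs(
    seq: list[str], offsets: Iterable[int], motif: str
) -> None:
    for off in offsets:
        seq[off:off + len(motif)] = list(motif)


def _choose_offsets(
    rng: np.random.Generator, region_len: int, n: int, motif_len: int = 4,
    spacing: int = 8, taken: set[int] | None = None,
) -> list[int]:
    """Non-overlapping motif start offsets within a region."""
    taken = taken if taken is not None else set()
    out: list[int] = []
    for _ in range(200):
        if len(out) >= n:
            break
        cand = int(rng.integers(0, region_len - motif_len))
        if all(abs(cand - t) >= spacing for t in taken):
            taken.add(cand)
            out.append(cand)
    return sorted(out)


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Synthetic gene models, splice events, genome and ground truth.

    Each gene carries a cassette exon and either a tandem-UTR pair (core +
    extension, one shared 5' boundary, two PASs) or an ALE pair.  UTR and
    exon sequences contain planted CELF (UGU-containing) and MBNL
    (GCU-containing) motif instances at recorded sense offsets.  Coordinates
    are 0-based, half-open, stranded.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chrSim"
    truth = SyntheticTruth(rbns_affinities=dict(DEFAULT_CELF_AFFINITIES))
    genes: list[GeneModel] = []
    events: list[SpliceEvent] = []
    genome_parts: list[str] = []
    cursor = 0
    T = config.n_timepoints

    # joint CELF/MBNL target assignment with planted co-occurrence
    p_c, p_m, f = config.p_celf_target, config.p_mbnl_target, config.cobind_factor
    p_both = min(f * p_c * p_m, min(p_c, p_m))
    p_celf_only = max(p_c - p_both, 0.0)
    p_mbnl_only = max(p_m - p_both, 0.0)
    p_neither = max(1.0 - p_both - p_celf_only - p_mbnl_only, 0.0)
    probs = np.array([p_both, p_celf_only, p_mbnl_only, p_neither])
    probs = probs / probs.sum()

    for gi in range(config.n_genes):
        gene_id = f"G{gi:04d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        utr_type = "tandem" if rng.random() < config.frac_tandem else "ale"
        exon_len = int(rng.integers(51, 250))

        layout = [
            ("exon1", config.exon1_len),
            ("upstream_intron", config.intron_len),
            ("exon", exon_len),
            ("downstream_intron", config.intron_len),
            ("last_pre", config.last_pre_len),
        ]
        if utr_type == "tandem":
            layout += [("core", config.core_len), ("extension", config.extension_len)]
        else:
            layout += [("ale1", config.ale_len), ("ale_spacer", config.ale_spacer),
                       ("ale2", config.ale_len)]
        sense_offsets: dict[str, tuple[int, int]] = {}
        pos = 0
        for name, length in layout:
            sense_offsets[name] = (pos, pos + length)
            pos += length
        gene_len = pos
        sense = list(rng.choice(list(BASES), size=gene_len))

        # --- plant binding sites -----------------------------------------
        kind = rng.choice(4, p=probs)
        is_celf = kind in (0, 1)
        is_mbnl = kind in (0, 2)
        celf_regions = (("core", "extension") if utr_type == "tandem"
                        else ("ale1", "ale2"))
        csites: dict[str, list[int]] = {}
        msites: dict[str, list[int]] = {}
        taken: dict[str, set[int]] = {r: set() for r in celf_regions}
        if is_celf:
            truth.celf_targets.add(gene_id)
            n_total = int(rng.integers(config.min_sites, 2 * config.max_sites + 1))
            split = rng.integers(0, n_total + 1)
            for region, n in zip(celf_regions, (split, n_total - split)):
                rlen = sense_offsets[region][1] - sense_offsets[region][0]
                offs = _choose_offsets(rng, rlen, int(n), taken=taken[region])
                if offs:
                    csites[region] = offs
        if is_mbnl:
            truth.mbnl_targets.add(gene_id)
            n_total = int(rng.integers(config.min_sites, 2 * config.max_sites + 1))
            split = rng.integers(0, n_total + 1)
            for region, n in zip(celf_regions, (split, n_total - split)):
                rlen = sense_offsets[region][1] - sense_offsets[region][0]
                offs = _choose_offsets(rng, rlen, int(n), taken=taken[region])
                if offs:
                    msites[region] = offs
        # planted proximal CELF/MBNL pair
        if is_celf and is_mbnl and csites and rng.random() < config.proximal_pair_fraction:
            region = next(iter(csites))
            anchor = csites[region][0]
            rlen = sense_offsets[region][1] - sense_offsets[region][0]
            for d in rng.permutation(np.arange(8, config.proximal_window)):
                cand = anchor + int(d)
                if cand + 4 <= rlen and all(abs(cand - t) >= 8 for t in taken[region]):
                    taken[region].add(cand)
                    msites.setdefault(region, []).append(cand)
                    msites[region].sort()
                    break

        # exonic CELF binding on the cassette exon
        exon_bound = rng.random() < config.exonic_bound_fraction
        if exon_bound:
            offs = _choose_offsets(rng, exon_len, int(rng.integers(1, 4)))
            if offs:
                csites["exon"] = offs

        for region, offs in csites.items():
            rs = sense_offsets[region][0]
            _plant_motifs(sense, [rs + o for o in offs], CELF_PLANT_MOTIF)
        for region, offs in msites.items():
            rs = sense_offsets[region][0]
            _plant_motifs(sense, [rs + o for o in offs], MBNL_PLANT_MOTIF)
        if csites:
            truth.celf_sites[gene_id] = csites
        if msites:
            truth.mbnl_sites[gene_id] = msites

        # --- genomic placement -------------------------------------------
        gene_start = cursor
        gene_end = cursor + gene_len
        sense_str = "".join(sense)
        genome_parts.append(sense_str if strand == "+" else _revcomp(sense_str))
        genome_parts.append("".join(rng.choice(list(BASES), size=config.gene_gap)))
        cursor = gene_end + config.gene_gap

        regions = {}
        for name, (s0, s1) in sense_offsets.items():
            if strand == "+":
                regions[name] = (gene_start + s0, gene_start + s1)
            else:
                regions[name] = (gene_end - s1, gene_end - s0)
        gene = GeneModel(gene_id, chrom, strand, gene_start, gene_end,
                         utr_type, regions, sense_offsets)
        genes.append(gene)

        # crosslink positions: central G of the planted UGU context (sense
        # offset +1 of each CELF motif), recorded as plus-strand coordinates
        xlinks = []
        for region, offs in csites.items():
            for o in offs:
                xlinks.append(gene.genomic_pos(region, o + 1))
        if xlinks:
            truth.crosslink_positions[gene_id] = sorted(xlinks)

        # --- events and PSI trajectories ---------------------------------
        se_id = f"{gene_id}_SE"
        events.append(SpliceEvent(
            se_id, "SE", gene_id, chrom, strand,
            {"exon": regions["exon"],
             "upstream_intron": regions["upstream_intron"],
             "downstream_intron": regions["downstream_intron"]},
        ))
        psi0 = float(rng.uniform(0.2, 0.8))
        if rng.random() < config.frac_monotone:
            if exon_bound:
                down = rng.random() < config.exonic_repression_rate
            else:
                down = rng.random() < 0.5
            delta = float(rng.uniform(0.25, 0.45)) * (-1 if down else 1)
            end_psi = float(np.clip(psi0 + delta, 0.02, 0.98))
            traj = np.linspace(psi0, end_psi, T)
            label = "monotone_down" if end_psi < psi0 else "monotone_up"
        else:
            traj = np.full(T, psi0)
            label = "flat"
        truth.psi_trajectories[se_id] = traj
        truth.trajectory_labels[se_id] = label

        utr_id = f"{gene_id}_UTR"
        if utr_type == "tandem":
            events.append(SpliceEvent(
                utr_id, "TandemUTR", gene_id, chrom, strand,
                {"core": regions["core"], "extension": regions["extension"]},
            ))
            n_core = len(csites.get("core", []))
            n_ext = len(csites.get("extension", []))
            psi0u = float(rng.uniform(0.4, 0.9))   # distal-isoform fraction
            if rng.random() < config.frac_monotone and (n_core or n_ext):
                if n_ext >= n_core:
                    down = rng.random() < config.proximal_shift_rate
                else:
                    down = rng.random() < 0.5
                delta = float(rng.uniform(0.2, 0.4)) * (-1 if down else 1)
                endu = float(np.clip(psi0u + delta, 0.02, 0.98))
                truth.psi_trajectories[utr_id] = np.linspace(psi0u, endu, T)
                truth.trajectory_labels[utr_id] = (
                    "monotone_down" if endu < psi0u else "monotone_up")
            else:
                truth.psi_trajectories[utr_id] = np.full(T, psi0u)
                truth.trajectory_labels[utr_id] = "flat"
        else:
            events.append(SpliceEvent(
                utr_id, "ALE", gene_id, chrom, strand,
                {"ale1": regions["ale1"], "ale2": regions["ale2"]},
            ))
            n1 = len(csites.get("ale1", []))
            n2 = len(csites.get("ale2", []))
            psi0u = float(rng.uniform(0.3, 0.7))   # ALE1 fraction
            if rng.random() < config.frac_monotone and (n1 or n2) and n1 != n2:
                # the more-bound ALE tends to lose share
                down = (n1 > n2) == (rng.random() < config.proximal_shift_rate)
                delta = float(rng.uniform(0.2, 0.4)) * (-1 if down else 1)
                endu = float(np.clip(psi0u + delta, 0.02, 0.98))
                truth.psi_trajectories[utr_id] = np.linspace(psi0u, endu, T)
                truth.trajectory_labels[utr_id] = (
                    "monotone_down" if endu < psi0u else "monotone_up")
            else:
                truth.psi_trajectories[utr_id] = np.full(T, psi0u)
                truth.trajectory_labels[utr_id] = "flat"

        # --- expression change from the potency model --------------------
        if utr_type == "tandem":
            psi_ext = float(truth.psi_trajectories[utr_id][0])
            model = -(config.potency_core * len(csites.get("core", []))
                      + config.potency_extension * len(csites.get("extension", []))
                      * psi_ext)
        else:
            psi1 = float(truth.psi_trajectories[utr_id][0])
            model = -config.potency_ale * (
                len(csites.get("ale1", [])) * psi1
                + len(csites.get("ale2", [])) * (1.0 - psi1))
        noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        truth.log_expression_change[gene_id] = model + noise

    genome = {chrom: "".join(genome_parts)}
    return Annotation(genome, genes, events, truth, config)


# ---------------------------------------------------------------------------
# time-course counts
# ---------------------------------------------------------------------------

def sample_ids(config: SimulationConfig) -> tuple[list[str], dict[str, int]]:
    labels = list(config.timepoint_labels[:config.n_timepoints])
    while len(labels) < config.n_timepoints:
        labels.append(f"t{len(labels)}")
    ids, order = [], {}
    for t, lab in enumerate(labels):
        for r in range(config.n_replicates):
            sid = f"{lab}_r{r + 1}"
            ids.append(sid)
            order[sid] = t
    return ids, order


def simulate_timecourse_counts(
    annotation: Annotation,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Per-event inclusion/exclusion counts and per-gene read counts.

    Inclusion counts are binomial draws of the event's true PSI at each time
    point (``read_depth`` trials per replicate); gene counts are lognormal
    around a baseline plus the potency-model log change interpolated linearly
    from control to endpoint.  Returns (splice counts, gene counts,
    sample -> time-point ordinal).
    """
    config = annotation.config
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    ids, order = sample_ids(config)
    T = config.n_timepoints
    srows, grows = [], []
    for event in annotation.events:
        traj = annotation.truth.psi_trajectories[event.event_id]
        for sid in ids:
            psi = float(traj[order[sid]])
            inc = int(rng.binomial(config.read_depth, psi))
            srows.append((event.event_id, sid, inc, config.read_depth - inc))
    for gene in annotation.genes:
        final = annotation.truth.log_expression_change[gene.gene_id]
        for sid in ids:
            frac = order[sid] / (T - 1) if T > 1 else 1.0
            mean_log = config.base_log_expression + final * frac
            count = rng.lognormal(mean=mean_log, sigma=config.count_noise_sd)
            grows.append((gene.gene_id, sid, int(round(count))))
    splice = pd.DataFrame(srows, columns=["event_id", "sample_id", "inclusion", "exclusion"])
    genes = pd.DataFrame(grows, columns=["gene_id", "sample_id", "count"])
    return splice, genes, order


# ---------------------------------------------------------------------------
# CLIP reads
# ---------------------------------------------------------------------------

def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


def simulate_clip_reads(
    annotation: Annotation,
    protein: str = "CELF1",
    seed: int | None = None,
) -> tuple[list[ClipRead], int]:
    """CLIP reads around planted binding sites plus uniform background.

    At each planted CELF site the central G of the UGU context carries a
    substitution with ``substitution_prob``; any read position mismatches at
    ``background_substitution_prob``.  Identical duplicate reads are emitted
    at ``duplicate_rate`` to exercise collapsing.  Returns the reads and the
    number of distinct mapped sequences among primary (non-duplicate) reads.
    """
    config = annotation.config
    rng = np.random.default_rng(
        (config.seed + (2 if protein == "CELF1" else 3)) if seed is None else seed)
    genome = annotation.genome
    L = config.clip_read_length
    site_table = (annotation.truth.celf_sites if protein == "CELF1"
                  else annotation.truth.mbnl_sites)
    sites: list[tuple[GeneModel, int]] = []   # (gene, plus-strand crosslink pos)
    for gene in annotation.genes:
        for region, offs in site_table.get(gene.gene_id, {}).items():
            for o in offs:
                xo = o + 1 if protein == "CELF1" else o  # G of UGU / of GCU
                sites.append((gene, gene.genomic_pos(region, xo)))

    n_total = config.clip_reads
    n_background = int(round(n_total * config.background_fraction))
    n_signal = n_total - n_background if sites else 0
    n_background = n_total - n_signal

    reads: list[ClipRead] = []
    primary_keys: set[tuple] = set()
    counter = 0

    def emit(gene: GeneModel, start: int, xpos: int | None) -> None:
        nonlocal counter
        start = int(np.clip(start, gene.start, gene.end - L))
        end = start + L
        chrom = gene.chrom
        subs = []
        if xpos is not None and start <= xpos < end and rng.random() < config.substitution_prob:
            ref = genome[chrom][xpos]
            subs.append((xpos - start, ref, _other_base(rng, ref)))
        if rng.random() < config.background_substitution_prob:
            off = int(rng.integers(0, L))
            if all(off != s[0] for s in subs):
                ref = genome[chrom][start + off]
                subs.append((off, ref, _other_base(rng, ref)))
        subs = tuple(sorted(subs))
        read = ClipRead(chrom, start, end, gene.strand, f"read{counter:07d}", subs)
        counter += 1
        reads.append(read)
        primary_keys.add((chrom, start, end, gene.strand, subs))
        if rng.random() < config.duplicate_rate:
            dup = ClipRead(chrom, start, end, gene.strand, f"read{counter:07d}", subs)
            counter += 1
            reads.append(dup)

    if n_signal:
        picks = rng.integers(0, len(sites), size=n_signal)
        for idx in picks:
            gene, xpos = sites[int(idx)]
            u = int(rng.integers(6, L - 6))
            start = xpos - u
            emit(gene, start, xpos)
    if n_background:
        lengths = np.array([g.end - g.start - L + 1 for g in annotation.genes], dtype=float)
        gp = lengths / lengths.sum()
        gidx = rng.choice(len(annotation.genes), size=n_background, p=gp)
        for gi in gidx:
            gene = annotation.genes[int(gi)]
            start = int(rng.integers(gene.start, max(gene.end - L, gene.start) + 1))
            emit(gene, start, None)
    return reads, len(primary_keys)


# ---------------------------------------------------------------------------
# RBNS libraries
# ---------------------------------------------------------------------------

def _affinity_vector(affinities: Mapping[str, float], k: int) -> np.ndarray:
    from .rbns import all_kmers

    vec = np.zeros(4 ** k)
    index = {km: i for i, km in enumerate(all_kmers(k))}
    for km, a in affinities.items():
        vec[index[km]] = a
    return vec


def _read_weights(arr: np.ndarray, affinity_vec: np.ndarray, k: int) -> np.ndarray:
    from .rbns import kmer_code_matrix

    codes = kmer_code_matrix(arr, k)
    return 1.0 + affinity_vec[codes].sum(axis=1)


def _decode(arr: np.ndarray) -> list[str]:
    lut = np.array(list("ACGU"))
    return ["".join(row) for row in lut[arr]]


def simulate_rbns_reads(
    affinities: Mapping[str, float] | None = None,
    concentration: str = "0nM",
    n_reads: int = 100_000,
    seed: int | None = 0,
    read_length: int = 40,
) -> tuple[list[str], list[str]]:
    """Input and pulldown RBNS libraries under a kmer-affinity model.

    Input reads are i.i.d. uniform RNA ``read_length``-mers; pulldown reads
    are resampled from an equally sized random pool with weight proportional
    to 1 + sum over kmers of affinity x occurrences.  The competitor
    ``concentration`` is metadata only: matching the observed invariance of
    CELF1 specificity, it does not alter the pulldown weights.
    """
    if n_reads < 1000:
        raise ValueError("n_reads must be >= 1000 (6mer count tables too sparse)")
    if affinities is None:
        affinities = DEFAULT_CELF_AFFINITIES
    k = len(next(iter(affinities))) if affinities else 6
    rng = np.random.default_rng(seed)
    input_arr = rng.integers(0, 4, size=(n_reads, read_length), dtype=np.uint8)
    pool = rng.integers(0, 4, size=(n_reads, read_length), dtype=np.uint8)
    weights = _read_weights(pool, _affinity_vector(affinities, k), k)
    probs = weights / weights.sum()
    picks = rng.choice(n_reads, size=n_reads, replace=True, p=probs)
    return _decode(input_arr), _decode(pool[picks])


def simulate_rbns_counts(
    affinities: Mapping[str, float] | None = None,
    n_reads: int = 1_000_000,
    seed: int | None = 0,
    read_length: int = 40,
    k: int = 6,
    chunk: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Input and pulldown kmer count vectors without materializing reads.

    Statistically identical to counting the output of
    :func:`simulate_rbns_reads` but chunked and vectorised, for the large
    library sizes where per-kmer frequencies need tight sampling error.
    Returns (input_counts, pulldown_counts), each of length 4**k in
    lexicographic ACGU kmer order.
    """
    from .rbns import count_kmer_codes, kmer_code_matrix

    if n_reads < 1000:
        raise ValueError("n_reads must be >= 1000 (6mer count tables too sparse)")
    if affinities is None:
        affinities = DEFAULT_CELF_AFFINITIES
    rng = np.random.default_rng(seed)
    vec = _affinity_vector(affinities, k) if affinities else np.zeros(4 ** k)
    inp_counts = np.zeros(4 ** k, dtype=np.int64)
    pull_counts = np.zeros(4 ** k, dtype=np.int64)
    done = 0
    while done < n_reads:
        n = min(chunk, n_reads - done)
        inp = rng.integers(0, 4, size=(n, read_length), dtype=np.uint8)
        inp_counts += count_kmer_codes(kmer_code_matrix(inp, k), k)
        pool = rng.integers(0, 4, size=(n, read_length), dtype=np.uint8)
        weights = _read_weights(pool, vec, k)
        picks = rng.choice(n, size=n, replace=True, p=weights / weights.sum())
        pull_counts += count_kmer_codes(kmer_code_matrix(pool[picks], k), k)
        done += n
    return inp_counts, pull_counts
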