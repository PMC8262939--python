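"""Calling complete RM systems from precomputed annotation evidence.

The inputs are tables produced upstream by profile (HMM) and local-alignment
searches of predicted proteins against reference methyltransferases and
endonucleases: one row per protein, per domain hit, per alignment hit.  This
module applies the genomic-context decision rules that turn that evidence
into counts of *complete* RM systems per genome:

1. overlapping profile hits on a protein are competed (>= 75% residue
   overlap; lower E-value wins);
2. alignment hits are accepted at >= 75% query coverage and E <= 1e-5;
3. proteins are role-classified (methyltransferase, endonuclease, fused,
   putative type IIG, specificity), with ResIII-like hits co-occurring with
   known false-positive covariate domains discarded;
4. a system is complete when an endonuclease lies within 4,000 bp of a
   methyltransferase on the same contig, or both activities fuse in one
   peptide; large (>750 aa) methyltransferase-only proteins are counted as
   putative type IIG single-protein systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "ProteinRecord",
    "DomainHit",
    "AlignmentHit",
    "RMSystemCall",
    "AnnotatedGenome",
    "compete_profiles",
    "accept_alignment",
    "classify_protein",
    "call_complete_systems",
    "count_rmpg",
    "annotate_genomes",
    "MAX_PAIR_GAP_BP",
    "MIN_IIG_LENGTH_AA",
    "PROFILE_OVERLAP_FRAC",
    "ALIGN_COVERAGE_FRAC",
    "ALIGN_MAX_EVALUE",
]

MAX_PAIR_GAP_BP = 4000        # REase-MTase pairing distance, inclusive
MIN_IIG_LENGTH_AA = 750       # strictly greater -> type IIG candidate
PROFILE_OVERLAP_FRAC = 0.75   # of the shorter envelope, inclusive
ALIGN_COVERAGE_FRAC = 0.75    # of the query length, inclusive
ALIGN_MAX_EVALUE = 1e-5       # inclusive


class Role(str, Enum):
    """Functional role of a hit or a classified protein."""

    MTASE = "MTase"
    REASE = "REase"
    SPECIFICITY = "specificity"
    RESIII = "ResIII"
    FP_COVARIATE = "FP-covariate"
    FUSED_RM = "fused_RM"
    PUTATIVE_IIG = "putative_IIG"
    NONE = "none"


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein with its gene coordinates (1-based, inclusive)."""

    protein_id: str
    genome_id: str
    contig_id: str
    gene_start: int
    gene_end: int
    strand: str
    length: int

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.protein_id}: gene_start > gene_end")
        if self.length <= 0:
            raise ValueError(f"{self.protein_id}: non-positive protein length")


@dataclass(frozen=True)
class DomainHit:
    """A profile (HMM) hit on a protein; envelope in residue coordinates."""

    protein_id: str
    profile_id: str
    env_start: int
    env_end: int
    evalue: float
    role: Role

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValueError(f"{self.protein_id}/{self.profile_id}: bad envelope")
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class AlignmentHit:
    """A local-alignment hit of a reference query protein against a target."""

    protein_id: str
    query_id: str
    query_length: int
    align_length: int
    evalue: float
    role: Role

    def __post_init__(self) -> None:
        if self.query_length <= 0 or self.align_length <= 0:
            raise ValueError("query_length and align_length must be > 0")


@dataclass(frozen=True)
class RMSystemCall:
    """One complete RM system: a gene pair, a fused peptide, or an IIG."""

    genome_id: str
    members: tuple[str, ...]
    kind: str  # paired | fused | putative_IIG


@dataclass
class AnnotatedGenome:
    """All evidence for one genome, the unit of RM-system calling."""

    genome_id: str
    proteins: list[ProteinRecord]
    domain_hits: list[DomainHit] = field(default_factory=list)
    alignment_hits: list[AlignmentHit] = field(default_factory=list)


def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    """Residue overlap as a fraction of the shorter envelope."""
    lo = max(a.env_start, b.env_start)
    hi = min(a.env_end, b.env_end)
    if hi < lo:
        return 0.0
    return (hi - lo + 1) / min(a.env_length, b.env_length)


def compete_profiles(hits: list[DomainHit]) -> list[DomainHit]:
    """Resolve overlapping profile hits on one protein.

    While any pair of retained hits overlaps on >= 75% of the shorter
    envelope's residues, the hit with the larger E-value is discarded
    (best-first elimination).  E-value ties break toward the longer
    envelope, then the lexicographically smaller profile id, so the result
    is independent of input order.
    """
    if not hits:
        return []
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    # best-first: sort by (evalue, -env_length, profile_id) and keep each hit
    # unless it overlaps an already-retained (better) one
    ranked = sorted(hits, key=lambda h: (h.evalue, -h.env_length, h.profile_id))
    kept: list[DomainHit] = []
    for h in ranked:
        if all(_overlap_fraction(h, k) < PROFILE_OVERLAP_FRAC for k in kept):
            kept.append(h)
    return kept


def accept_alignment(hit: AlignmentHit) -> bool:
    """Alignment acceptance: >= 75% query coverage and E <= 1e-5."""
    return (
        hit.align_length >= ALIGN_COVERAGE_FRAC * hit.query_length
        and hit.evalue <= ALIGN_MAX_EVALUE
    )


def classify_protein(
    protein: ProteinRecord,
    domain_hits: list[DomainHit],
    alignment_hits: list[AlignmentHit] = (),
) -> Role:
    """Assign a single functional role from competed/filtered evidence.

    Evidence for both activities on one peptide makes a fused RM system.  A
    methyltransferase-only protein longer than 750 aa is a putative type IIG
    candidate (size separates IIG enzymes from plain methyltransferases).
    ResIII-like endonuclease motifs recur in helicases and transcriptional
    regulators; such a hit accompanied by any known false-positive covariate
    domain on the same protein is discarded entirely.
    """
    domain_hits = compete_profiles(list(domain_hits))
    roles = {h.role for h in domain_hits}
    for ah in alignment_hits:
        if accept_alignment(ah):
            roles.add(ah.role)
    has_fp = Role.FP_COVARIATE in roles
    has_resiii = Role.RESIII in roles
    if has_resiii and not has_fp:
        roles.add(Role.REASE)
    roles -= {Role.RESIII, Role.FP_COVARIATE}
    has_mtase = Role.MTASE in roles
    has_rease = Role.REASE in roles
    if has_mtase and has_rease:
        return Role.FUSED_RM
    if has_mtase:
        if protein.length > MIN_IIG_LENGTH_AA:
            return Role.PUTATIVE_IIG
        return Role.MTASE
    if has_rease:
        return Role.REASE
    if Role.SPECIFICITY in roles:
        return Role.SPECIFICITY
    return Role.NONE


def _gene_gap(a: ProteinRecord, b: ProteinRecord) -> int:
    """Bp between the closest gene boundaries; 0 for overlapping genes."""
    if a.gene_end < b.gene_start:
        return b.gene_start - a.gene_end - 1
    if b.gene_end < a.gene_start:
        return a.gene_start - b.gene_end - 1
    return 0


def call_complete_systems(genome: AnnotatedGenome) -> list[RMSystemCall]:
    """Enumerate complete RM systems in one genome.

    Fused and putative-IIG proteins each stand alone as a complete system.
    Remaining endonucleases pair greedily with the nearest free
    methyltransferase on the same contig within 4,000 bp (gap between the
    closest gene boundaries, inclusive; strand ignored); each protein joins
    at most one call.  Orphan enzymes yield nothing.
    """
    by_id = {p.protein_id: p for p in genome.proteins}
    dom_by_protein: dict[str, list[DomainHit]] = {}
    for h in genome.domain_hits:
        if h.protein_id not in by_id:
            raise ValueError(f"domain hit references unknown protein {h.protein_id}")
        dom_by_protein.setdefault(h.protein_id, []).append(h)
    ali_by_protein: dict[str, list[AlignmentHit]] = {}
    for a in genome.alignment_hits:
        if a.protein_id not in by_id:
            raise ValueError(f"alignment hit references unknown protein {a.protein_id}")
        ali_by_protein.setdefault(a.protein_id, []).append(a)

    calls: list[RMSystemCall] = []
    mtases: list[ProteinRecord] = []
    reases: list[ProteinRecord] = []
    for p in sorted(genome.proteins, key=lambda q: (q.contig_id, q.gene_start, q.protein_id)):
        role = classify_protein(
            p, dom_by_protein.get(p.protein_id, []), ali_by_protein.get(p.protein_id, [])
        )
        if role is Role.FUSED_RM:
            calls.append(RMSystemCall(genome.genome_id, (p.protein_id,), "fused"))
        elif role is Role.PUTATIVE_IIG:
            calls.append(RMSystemCall(genome.genome_id, (p.protein_id,), "putative_IIG"))
        elif role is Role.MTASE:
            mtases.append(p)
        elif role is Role.REASE:
            reases.append(p)

    # greedy nearest-first one-to-one pairing within each contig
    candidates = []
    for r in reases:
        for m in mtases:
            if r.contig_id != m.contig_id:
                continue
            gap = _gene_gap(r, m)
            if gap <= MAX_PAIR_GAP_BP:
                candidates.append((gap, r.gene_start, m.gene_start, r.protein_id, m.protein_id))
    used: set[str] = set()
    for gap, _, _, r_id, m_id in sorted(candidates):
        if r_id in used or m_id in used:
            continue
        used.update((r_id, m_id))
        calls.append(RMSystemCall(genome.genome_id, (r_id, m_id), "paired"))
    return calls


def count_rmpg(
    calls_by_genome: dict[str, list[RMSystemCall]],
    include_putative_iig: bool = True,
) -> pd.DataFrame:
    """Per-genome totals of complete RM systems.

    Returns a frame indexed by genome with columns ``n_paired``, ``n_fused``,
    ``n_putative_iig``, ``rm_total`` and ``rm_total_no_iig``; the latter is
    the stricter count that drops the size-based type IIG candidates.
    """
    rows = []
    for genome_id, calls in calls_by_genome.items():
        kinds = pd.Series([c.kind for c in calls], dtype=object)
        n_paired = int((kinds == "paired").sum())
        n_fused = int((kinds == "fused").sum())
        n_iig = int((kinds == "putative_IIG").sum())
        total = n_paired + n_fused + (n_iig if include_putative_iig else 0)
        rows.append(
            {
                "genome_id": genome_id,
                "n_paired": n_paired,
                "n_fused": n_fused,
                "n_putative_iig": n_iig,
                "rm_total": total,
                "rm_total_no_iig": n_paired + n_fused,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "n_paired", "n_fused", "n_putative_iig",
            "rm_total", "rm_total_no_iig",
        ],
    ).set_index("genome_id")


def annotate_genomes(
    proteins: pd.DataFrame,
    domain_hits: pd.DataFrame,
    alignment_hits: pd.DataFrame,
) -> pd.DataFrame:
    """Full pipeline over evidence tables: returns per-genome RM counts.

    Expected columns are documented in :mod:`rmeco.io` (the TSV schemas);
    this function accepts any DataFrames with those columns.
    """
    genomes: dict[str, AnnotatedGenome] = {}
    for row in proteins.itertuples(index=False):
        rec = ProteinRecord(
            protein_id=str(row.protein_id),
            genome_id=str(row.genome_id),
            contig_id=str(row.contig_id),
            gene_start=int(row.gene_start),
            gene_end=int(row.gene_end),
            strand=str(row.strand),
            length=int(row.length),
        )
        genomes.setdefault(rec.genome_id, AnnotatedGenome(rec.genome_id, [])).proteins.append(rec)
    protein_to_genome = {
        p.protein_id: g.genome_id for g in genomes.values() for p in g.proteins
    }
    for row in domain_hits.itertuples(index=False):
        hit = DomainHit(
            protein_id=str(row.protein_id),
            profile_id=str(row.profile_id),
            env_start=int(row.env_start),
            env_end=int(row.env_end),
            evalue=float(row.evalue),
            role=Role(row.role),
        )
        genomes[protein_to_genome[hit.protein_id]].domain_hits.append(hit)
    for row in alignment_hits.itertuples(index=False):
        hit = AlignmentHit(
            protein_id=str(row.protein_id),
            query_id=str(row.query_id),
            query_length=int(row.query_length),
            align_length=int(row.align_length),
            evalue=float(row.evalue),
            role=Role(row.role),
        )
        genomes[protein_to_genome[hit.protein_id]].alignment_hits.append(hit)
    calls = {gid: call_complete_systems(g) for gid, g in sorted(genomes.items())}
    counts = count_rmpg(calls)
    counts.insert(
        0,
        "n_contigs",
        pd.Series(
            {gid: len({p.contig_id for p in g.proteins}) for gid, g in genomes.items()}
        ),
    )
    return counts
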