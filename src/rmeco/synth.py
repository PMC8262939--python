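"""Synthetic fixtures with planted ground truth.

Two generators:

* :func:`gen_annotation_fixture` builds protein/domain-hit/alignment-hit
  evidence tables containing planted complete RM systems (gene pairs,
  fused peptides, putative type IIG proteins) plus adversarial decoys that
  each violate exactly one calling rule at its boundary (a pair 4,001 bp
  apart, an alignment at 74% coverage or E = 1.1e-5, a 750-aa
  methyltransferase, a ResIII hit with a false-positive covariate, a worse
  duplicate profile overlapping >= 80%).  The companion truth table gives
  the intended per-genome counts, so the calling rules' boundary semantics
  are pinned by construction.

* :func:`gen_stats_tables` draws isolate-level RM counts from a known
  generating model (negative-binomial with log link on genome size, or
  linear with Gaussian noise) so regression recovery can be scored against
  the generating parameters.

Both are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    ALIGN_MAX_EVALUE,
    MAX_PAIR_GAP_BP,
    MIN_IIG_LENGTH_AA,
    Role,
)

__all__ = [
    "AnnotationFixtureConfig",
    "StatsFixtureConfig",
    "gen_annotation_fixture",
    "gen_stats_tables",
]

PROTEIN_COLUMNS = [
    "protein_id", "genome_id", "contig_id", "gene_start", "gene_end", "strand", "length",
]
DOMHIT_COLUMNS = ["protein_id", "profile_id", "env_start", "env_end", "evalue", "role"]
ALIHIT_COLUMNS = ["protein_id", "query_id", "query_length", "align_length", "evalue", "role"]


@dataclass(frozen=True)
class AnnotationFixtureConfig:
    seed: int = 0
    n_genomes: int = 5
    n_paired: int = 2          # planted REase-MTase gene pairs per genome
    n_fused: int = 1           # planted fused peptides per genome
    n_putative_iig: int = 1    # planted >750-aa MTase-only proteins per genome
    n_decoys: int = 4          # boundary-violating decoys per genome
    contigs_per_genome: int = 2
    gene_length_bp: tuple[int, int] = (900, 2400)
    pair_gap_bp: tuple[int, int] = (0, 3900)  # strictly inside the 4,000-bp rule
    intergenic_bp: int = 6000  # spacing between planted items; > pairing reach

    def __post_init__(self) -> None:
        if min(self.n_genomes, self.contigs_per_genome) < 1:
            raise ValueError("need at least one genome and one contig")
        if min(self.n_paired, self.n_fused, self.n_putative_iig, self.n_decoys) < 0:
            raise ValueError("planted counts must be >= 0")
        if self.pair_gap_bp[1] > MAX_PAIR_GAP_BP:
            raise ValueError("planted pair gaps would leave the complete-system rule")
        if self.intergenic_bp <= MAX_PAIR_GAP_BP:
            raise ValueError(
                "intergenic spacing must exceed the pairing distance or decoys "
                "could satisfy the rules accidentally"
            )


@dataclass(frozen=True)
class StatsFixtureConfig:
    seed: int = 0
    n_genera: int = 200
    isolates_per_genus: tuple[int, int] = (1, 30)
    genome_size_mbp: tuple[float, float] = (1.0, 10.0)
    model: str = "negbin"          # "negbin" | "linear"
    slope: float = 0.1             # per Mbp (log-link for negbin)
    intercept: float = 0.5         # log-scale for negbin, counts for linear
    dispersion: float = 0.3        # NB alpha; variance = mu + alpha mu^2
    noise_sd: float = 1.0          # linear model only
    group_shift: float = 0.0       # additive shift for the "eutrophic" group

    def __post_init__(self) -> None:
        if self.n_genera < 2:
            raise ValueError("need at least two genera")
        if self.model not in ("negbin", "linear"):
            raise ValueError(f"unknown generating model {self.model!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


class _GenomeBuilder:
    """Lays planted genes left-to-right along contigs with safe spacing."""

    def __init__(self, genome_id: str, cfg: AnnotationFixtureConfig, rng: np.random.Generator):
        self.genome_id = genome_id
        self.cfg = cfg
        self.rng = rng
        self.cursor = {f"{genome_id}_c{k}": 1 for k in range(cfg.contigs_per_genome)}
        self.contigs = list(self.cursor)
        self.n_proteins = 0
        self.proteins: list[dict] = []
        self.domhits: list[dict] = []
        self.alihits: list[dict] = []

    def new_gene(self, contig: str, length_aa: int, gap_bp: int | None = None) -> dict:
        if gap_bp is None:
            gap_bp = self.cfg.intergenic_bp
        # +1 so the boundary-to-boundary gap equals gap_bp exactly
        start = self.cursor[contig] + gap_bp + 1
        end = start + length_aa * 3 + 2  # CDS length incl. stop
        self.cursor[contig] = end
        self.n_proteins += 1
        rec = {
            "protein_id": f"{self.genome_id}_p{self.n_proteins:04d}",
            "genome_id": self.genome_id,
            "contig_id": contig,
            "gene_start": start,
            "gene_end": end,
            "strand": "+" if self.rng.random() < 0.5 else "-",
            "length": length_aa,
        }
        self.proteins.append(rec)
        return rec

    def gene_length(self) -> int:
        lo, hi = self.cfg.gene_length_bp
        return int(self.rng.integers(lo, hi + 1)) // 3

    def mtase_length(self) -> int:
        # separate methyltransferases must stay at or below the type IIG
        # size rule or they would be called putative IIG
        return min(self.gene_length(), MIN_IIG_LENGTH_AA - 50)

    def add_domhit(self, protein: dict, role: Role, *, evalue: float | None = None,
                   env: tuple[int, int] | None = None, tag: str = "") -> dict:
        if evalue is None:
            evalue = 10.0 ** self.rng.uniform(-30, -8)
        if env is None:
            span = max(protein["length"] // 2, 40)
            start = int(self.rng.integers(1, max(protein["length"] - span, 2)))
            env = (start, min(start + span, protein["length"]))
        hit = {
            "protein_id": protein["protein_id"],
            "profile_id": f"PF_{role.value}{tag}_{len(self.domhits):03d}",
            "env_start": env[0],
            "env_end": env[1],
            "evalue": evalue,
            "role": role.value,
        }
        self.domhits.append(hit)
        return hit


def gen_annotation_fixture(
    config: AnnotationFixtureConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (proteins, domain_hits, alignment_hits, truth) tables.

    ``truth`` holds the planted per-genome counts: columns ``genome_id``,
    ``n_paired``, ``n_fused``, ``n_putative_iig``, ``rm_total``,
    ``rm_total_no_iig``.
    """
    rng = np.random.default_rng(config.seed)
    all_p, all_d, all_a, truth = [], [], [], []
    for g in range(config.n_genomes):
        gid = f"G{g:03d}"
        b = _GenomeBuilder(gid, config, rng)
        # planted REase-MTase pairs, gap within the rule with margin
        for _ in range(config.n_paired):
            contig = b.contigs[int(rng.integers(len(b.contigs)))]
            rease = b.new_gene(contig, b.gene_length())
            gap = int(rng.integers(config.pair_gap_bp[0], config.pair_gap_bp[1] + 1))
            mtase = b.new_gene(contig, b.mtase_length(), gap_bp=gap)
            b.add_domhit(rease, Role.REASE)
            b.add_domhit(mtase, Role.MTASE)
        # planted fused peptides: both motifs, one protein
        for _ in range(config.n_fused):
            contig = b.contigs[int(rng.integers(len(b.contigs)))]
            fused = b.new_gene(contig, max(b.gene_length(), 500))
            half = fused["length"] // 2
            b.add_domhit(fused, Role.REASE, env=(1, half - 20))
            b.add_domhit(fused, Role.MTASE, env=(half + 20, fused["length"]))
        # planted putative type IIG: MTase-only, strictly > 750 aa
        for _ in range(config.n_putative_iig):
            contig = b.contigs[int(rng.integers(len(b.contigs)))]
            iig = b.new_gene(contig, int(rng.integers(MIN_IIG_LENGTH_AA + 1, 1400)))
            b.add_domhit(iig, Role.MTASE)
        # an evidence wrinkle the competition rule must survive: duplicate
        # worse-scoring profile on a planted protein, overlapping >= 80%
        if b.proteins:
            target = b.proteins[int(rng.integers(len(b.proteins)))]
            base = next(h for h in b.domhits if h["protein_id"] == target["protein_id"])
            span = base["env_end"] - base["env_start"]
            b.add_domhit(
                target,
                Role(base["role"]),
                evalue=base["evalue"] * 1e3,
                env=(base["env_start"], base["env_start"] + max(int(span * 0.9), 1)),
                tag="dup",
            )
        _plant_decoys(b, config, rng)
        all_p.extend(b.proteins)
        all_d.extend(b.domhits)
        all_a.extend(b.alihits)
        total = config.n_paired + config.n_fused + config.n_putative_iig
        truth.append(
            {
                "genome_id": gid,
                "n_paired": config.n_paired,
                "n_fused": config.n_fused,
                "n_putative_iig": config.n_putative_iig,
                "rm_total": total,
                "rm_total_no_iig": total - config.n_putative_iig,
            }
        )
    proteins = pd.DataFrame(all_p, columns=PROTEIN_COLUMNS)
    domhits = pd.DataFrame(all_d, columns=DOMHIT_COLUMNS)
    alihits = pd.DataFrame(all_a, columns=ALIHIT_COLUMNS)
    return proteins, domhits, alihits, pd.DataFrame(truth)


def _plant_decoys(b: _GenomeBuilder, config: AnnotationFixtureConfig, rng) -> None:
    """Each decoy violates exactly one rule, at its boundary where possible."""
    kinds = ["gap_4001", "orphan_mtase", "orphan_rease", "resiii_fp",
             "align_low_coverage", "align_high_evalue", "mtase_750aa"]
    for k in range(config.n_decoys):
        kind = kinds[k % len(kinds)]
        contig = b.contigs[int(rng.integers(len(b.contigs)))]
        if kind == "gap_4001":
            rease = b.new_gene(contig, b.gene_length())
            mtase = b.new_gene(contig, b.mtase_length(), gap_bp=MAX_PAIR_GAP_BP + 1)
            b.add_domhit(rease, Role.REASE)
            b.add_domhit(mtase, Role.MTASE)
        elif kind == "orphan_mtase":
            b.add_domhit(b.new_gene(contig, b.mtase_length()), Role.MTASE)
        elif kind == "orphan_rease":
            b.add_domhit(b.new_gene(contig, b.gene_length()), Role.REASE)
        elif kind == "resiii_fp":
            helicase = b.new_gene(contig, b.gene_length())
            b.add_domhit(helicase, Role.RESIII)
            b.add_domhit(helicase, Role.FP_COVARIATE,
                         env=(1, max(helicase["length"] // 4, 10)))
        elif kind == "align_low_coverage":
            p = b.new_gene(contig, b.gene_length())
            b.alihits.append({
                "protein_id": p["protein_id"], "query_id": f"gold_{k}",
                "query_length": 100, "align_length": 74,
                "evalue": 1e-20, "role": Role.MTASE.value,
            })
        elif kind == "align_high_evalue":
            p = b.new_gene(contig, b.gene_length())
            b.alihits.append({
                "protein_id": p["protein_id"], "query_id": f"gold_{k}",
                "query_length": 100, "align_length": 95,
                "evalue": ALIGN_MAX_EVALUE * 1.1, "role": Role.REASE.value,
            })
        elif kind == "mtase_750aa":
            # exactly 750 aa: MTase-only but NOT > 750, so a plain orphan MTase
            b.add_domhit(b.new_gene(contig, MIN_IIG_LENGTH_AA), Role.MTASE)


def gen_stats_tables(
    config: StatsFixtureConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (isolate_table, genus_table, truth) for the statistics module.

    Isolate RM counts are drawn per the generating model given genome size;
    genome sizes are uniform on the configured Mbp range with small
    within-genus jitter.  When ``group_shift`` is nonzero, half the genera
    are labelled ``eutrophic`` and their linear predictor is shifted up by
    ``group_shift``, giving a known two-group difference for rank-sum tests.
    """
    rng = np.random.default_rng(config.seed)
    lo_n, hi_n = config.isolates_per_genus
    rows = []
    for g in range(config.n_genera):
        genus = f"genus_{g:04d}"
        habitat = "eutrophic" if (config.group_shift != 0 and g % 2 == 0) else "oligotrophic"
        size_mbp = rng.uniform(*config.genome_size_mbp)
        n_iso = int(rng.integers(lo_n, hi_n + 1))
        for i in range(n_iso):
            iso_size = size_mbp * (1.0 + 0.02 * rng.standard_normal())
            eta = config.intercept + config.slope * iso_size
            if habitat == "eutrophic":
                eta += config.group_shift
            if config.model == "negbin":
                mu = np.exp(eta)
                size = 1.0 / config.dispersion
                lam = rng.gamma(shape=size, scale=mu / size)
                count = int(rng.poisson(lam))
            else:
                count = max(0, int(round(eta + config.noise_sd * rng.standard_normal())))
            count_no_iig = int(rng.binomial(count, 0.8)) if count else 0
            rows.append(
                {
                    "assembly_id": f"{genus}_a{i:03d}",
                    "genus": genus,
                    "phylum": "synthetic",
                    "genome_size": iso_size * 1e6,
                    "rm_total": count,
                    "rm_total_no_iig": count_no_iig,
                    "habitat": habitat,
                }
            )
    isolates = pd.DataFrame(rows)
    from .stats import aggregate_genus

    genus_table = aggregate_genus(isolates)
    truth = {
        "model": config.model,
        "slope": config.slope,
        "intercept": config.intercept,
        "dispersion": config.dispersion if config.model == "negbin" else None,
        "group_shift": config.group_shift,
    }
    return isolates, genus_table, truth
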