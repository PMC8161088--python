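"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without external downloads:

* **genotypes** — haplotypes drawn per block with a tunable within-block
  allelic correlation (an anchor SNP is drawn at its allele frequency;
  linked SNPs copy the anchor allele with probability sqrt(r2_target),
  otherwise redraw at their own frequency — this leaves marginal
  frequencies intact when block members share a frequency and gives
  haplotype correlation exactly sqrt(r2), hence r^2 equal to the target);
* **disease** — a single-causal-SNP logistic model: per-alt-allele log-odds
  ln(disease_or), intercept solved so the population prevalence matches a
  configurable baseline; individuals are drawn until the case and control
  quotas fill;
* **expression** — additive eQTL effect plus Gaussian noise,
  ``expr = nes * dosage + N(0, sd)``;
* **Hi-C** — Poisson counts around a power-law distance decay
  ``C * (|i-j|+1)^(-alpha)`` with an optional planted loop (fold-enrichment
  at one bin pair).

The module also emits the in-study fixture tables (replication genotype
counts, the coding-variant table, the CCR5-Delta32 frequency comparison) in
the file formats the other modules consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .annotation import VariantRecord
from .assoc import CohortGenotypes
from .errors import InputError
from .hic import ContactMatrix
from .popgen import GenotypeCounts

__all__ = [
    "SnpSpec",
    "BlockSpec",
    "HicSpec",
    "SimConfig",
    "simulate_haplotypes",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_expression",
    "simulate_contact_matrix",
    "emit_fixtures",
    "simulate_locus_inputs",
    "table1_cohort",
    "table3_cohort",
    "table2_variants",
    "DELTA32",
]


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    pos: int
    maf: float
    ref: str = "T"
    alt: str = "C"
    chrom: str = "chr3"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise InputError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class BlockSpec:
    """SNPs sharing a haplotype block; first SNP is the anchor.

    ``r2`` is the target squared allelic correlation between the anchor and
    every other SNP of the block.
    """

    snp_ids: tuple
    r2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise InputError(f"block r2 must be in [0, 1], got {self.r2}")
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))


@dataclass(frozen=True)
class HicSpec:
    n_bins: int = 20
    bin_size: int = 40_000
    start: int = 46_000_000
    chrom: str = "chr3"
    decay_exponent: float = 1.0
    scale: float = 100.0
    loop: tuple | None = None  # (bin_i, bin_j, fold), fold >= 1

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise InputError("decay_exponent must be > 0")
        if self.loop is not None and self.loop[2] < 1:
            raise InputError("loop fold must be >= 1")


# Defaults mirror the study scales: a 3p21.31-like locus, lead-SNP MAF ~0.16,
# replication cohort of 202 cases / 929 controls, GWAS odds ratio 1.32,
# lung eQTL panel of 208 samples with a negative effect on expression.
def _default_panel() -> tuple:
    return (
        SnpSpec("rs9845542", 46_270_000, 0.17),
        SnpSpec("rs12639314", 46_320_000, 0.17),
        SnpSpec("rs35951367", 46_349_000, 0.16),
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_cases: int = 202
    n_controls: int = 929
    snp_panel: tuple = field(default_factory=_default_panel)
    haplotype_blocks: tuple = ()
    causal_snp: str = "rs35951367"
    disease_or: float = 1.32
    baseline_prevalence: float = 0.05
    eqtl_nes: float = -0.3
    expr_noise_sd: float = 1.0
    n_eqtl_samples: int = 208
    hic: HicSpec = field(default_factory=HicSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_panel", tuple(self.snp_panel))
        blocks = self.haplotype_blocks
        if not blocks:
            # default: all panel SNPs in one tightly linked block
            blocks = (BlockSpec(tuple(s.snp_id for s in self.snp_panel), r2=1.0),)
        object.__setattr__(self, "haplotype_blocks", tuple(blocks))
        ids = [s.snp_id for s in self.snp_panel]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate SNP ids in panel")
        covered = [sid for b in self.haplotype_blocks for sid in b.snp_ids]
        if sorted(covered) != sorted(ids):
            raise InputError("haplotype blocks must partition the SNP panel")
        if self.causal_snp not in ids:
            raise InputError(f"causal SNP {self.causal_snp!r} not in panel")
        if self.disease_or <= 0:
            raise InputError("disease_or must be > 0")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise InputError("baseline_prevalence must be in (0, 1)")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snp_panel]

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "snp_panel" in d:
            d["snp_panel"] = tuple(SnpSpec(**s) for s in d["snp_panel"])
        if "haplotype_blocks" in d:
            d["haplotype_blocks"] = tuple(BlockSpec(**b) for b in d["haplotype_blocks"])
        if "hic" in d and not isinstance(d["hic"], HicSpec):
            h = dict(d["hic"])
            if "loop" in h and h["loop"] is not None:
                h["loop"] = tuple(h["loop"])
            d["hic"] = HicSpec(**h)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _rng(cfg_or_seed, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(seed)


def simulate_haplotypes(cfg: SimConfig, n_haps: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_haps`` haplotypes (0/1 alt indicators) over the SNP panel."""
    maf = {s.snp_id: s.maf for s in cfg.snp_panel}
    col = {sid: i for i, sid in enumerate(cfg.snp_ids)}
    H = np.zeros((n_haps, len(col)), dtype=np.int8)
    for block in cfg.haplotype_blocks:
        anchor = block.snp_ids[0]
        a = rng.random(n_haps) < maf[anchor]
        H[:, col[anchor]] = a
        phi = math.sqrt(block.r2)
        for sid in block.snp_ids[1:]:
            copy = rng.random(n_haps) < phi
            own = rng.random(n_haps) < maf[sid]
            H[:, col[sid]] = np.where(copy, a, own)
    return H


def simulate_genotypes(cfg: SimConfig, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Diploid genotype (alt-dosage) matrix of a population sample, n x n_snps."""
    rng = _rng(cfg, rng)
    H = simulate_haplotypes(cfg, 2 * n, rng)
    return (H[0::2] + H[1::2]).astype(np.int8)


def simulate_cohort(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    max_draws: int = 20_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a case-control cohort under the logistic disease model.

    Individuals are drawn from the population until ``n_cases`` cases and
    ``n_controls`` controls accumulate; the returned genotype matrix lists
    cases first, then controls, with the phenotype vector (1 = case)
    aligned.  Exceeding ``max_draws`` raises :class:`InputError` (quota
    unattainable at the configured prevalence).
    """
    rng = _rng(cfg, rng)
    lor = math.log(cfg.disease_or)
    causal_idx = cfg.snp_ids.index(cfg.causal_snp)
    q = cfg.snp_panel[causal_idx].maf
    gprob = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])

    if lor == 0.0:
        b0 = math.log(cfg.baseline_prevalence / (1 - cfg.baseline_prevalence))
    else:
        b0 = brentq(
            lambda b: float((gprob * expit(b + lor * np.arange(3))).sum())
            - cfg.baseline_prevalence,
            -50.0,
            50.0,
        )

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    need_ca, need_co = cfg.n_cases, cfg.n_controls
    drawn = 0
    chunk = max(4096, need_ca + need_co)
    while need_ca > 0 or need_co > 0:
        if drawn >= max_draws:
            raise InputError(
                f"case/control quota not reached after {drawn} draws; "
                "prevalence too extreme for the requested cohort"
            )
        G = simulate_genotypes(cfg, chunk, rng)
        drawn += chunk
        p_case = expit(b0 + lor * G[:, causal_idx])
        is_case = rng.random(chunk) < p_case
        if need_ca > 0:
            take = G[is_case][:need_ca]
            cases.append(take)
            need_ca -= take.shape[0]
        if need_co > 0:
            take = G[~is_case][:need_co]
            controls.append(take)
            need_co -= take.shape[0]

    G = np.vstack(cases + controls)
    y = np.concatenate([np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)])
    return G, y


def simulate_expression(
    genotypes: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expression vector with an additive effect of the causal SNP's dosage."""
    rng = _rng(cfg, rng)
    G = np.atleast_2d(np.asarray(genotypes))
    dosage = G[:, cfg.snp_ids.index(cfg.causal_snp)].astype(float)
    noise = rng.normal(0.0, cfg.expr_noise_sd, size=dosage.size) if cfg.expr_noise_sd > 0 else 0.0
    return cfg.eqtl_nes * dosage + noise


def simulate_contact_matrix(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    tissue: str = "",
) -> ContactMatrix:
    """Poisson contact matrix with power-law decay and an optional planted loop."""
    rng = _rng(cfg, rng)
    h = cfg.hic
    idx = np.arange(h.n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = h.scale * (dist + 1.0) ** (-h.decay_exponent)
    if h.loop is not None:
        i, j, fold = h.loop
        lam[i, j] *= fold
        lam[j, i] *= fold
    upper = np.triu(rng.poisson(lam).astype(float))
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(
        chrom=h.chrom, bin_size=h.bin_size, start_bin_pos=h.start, counts=counts, tissue=tissue
    )


# ---------------------------------------------------------------------------
# In-study fixture tables (replication counts, coding variants, Delta32).
# These are fixed published inputs consumed as-is by the association and
# filtering stages.

#: CCR5-Delta32 allele-frequency comparison: WES cases vs public exome controls
DELTA32 = {"freq_cases": 0.1020, "n_cases": 147, "freq_controls": 0.1022, "n_controls": 1095}


def table1_cohort() -> CohortGenotypes:
    """Replication cohort genotype counts for the lead regulatory SNP
    (202 cases: TT/TC/CC = 120/72/10; 929 controls: 625/266/38; minor allele C)."""
    return CohortGenotypes(
        case_counts=GenotypeCounts(120, 72, 10),
        control_counts=GenotypeCounts(625, 266, 38),
        minor_allele="C",
    )


def table3_cohort() -> CohortGenotypes:
    """Rare coding-variant cohort counts (221 cases: GG/GT/TT = 217/4/0;
    1084 controls: 1079/5/0; minor allele T)."""
    return CohortGenotypes(
        case_counts=GenotypeCounts(217, 4, 0),
        control_counts=GenotypeCounts(1079, 5, 0),
        minor_allele="T",
    )


def table2_variants(include_decoys: bool = False) -> list[VariantRecord]:
    """The four rare CCR5 coding variants found in six exome-sequenced patients.

    Population AFs other than the lead rare variant's published 0.03% (NFE)
    are synthetic placeholders below every filtering threshold.  With
    ``include_decoys`` two synthetic rejects are appended: a synonymous SNV
    and a common (AF 2%) missense variant.
    """
    variants = [
        VariantRecord(
            "rs1800452", "chr3", 46_415_061, "G", "A", "nonsynonymous_SNV",
            pop_af=0.00005, carriers=(("R-16", "0/1"),),
            annotations={"aa_change": "p.R223Q", "cadd": "22.5"},
        ),
        VariantRecord(
            "rs56198941", "chr3", 46_414_611, "C", "T", "nonsynonymous_SNV",
            pop_af=0.00005, carriers=(("R-68", "0/1"),),
            annotations={"aa_change": "p.A73V", "cadd": "31"},
        ),
        VariantRecord(
            "rs774845977", "chr3", 46_415_073, "AGA", "-", "nonframeshift_indel",
            pop_af=None, carriers=(("R-135", "0/1"),),
            annotations={"aa_change": "p.K229del"},
        ),
        VariantRecord(
            "rs34418657", "chr3", 46_414_784, "G", "T", "nonsynonymous_SNV",
            pop_af=0.0003, carriers=(("R-30", "0/1"), ("R-60", "0/1"), ("R-72", "0/1")),
            annotations={"aa_change": "p.V131F", "cadd": "29.8"},
        ),
    ]
    if include_decoys:
        variants += [
            VariantRecord(
                "rs_syn_decoy", "chr3", 46_414_700, "A", "G", "synonymous_SNV",
                pop_af=0.0, carriers=(("R-01", "0/1"),),
            ),
            VariantRecord(
                "rs_common_decoy", "chr3", 46_414_900, "C", "G", "nonsynonymous_SNV",
                pop_af=0.02, carriers=(("R-02", "0/1"),),
            ),
        ]
    return variants


def _write_counts(path: Path, cohort: CohortGenotypes) -> None:
    with open(path, "w") as fh:
        fh.write("arm\tn_AA\tn_Aa\tn_aa\n")
        for arm, g in (("cases", cohort.case_counts), ("controls", cohort.control_counts)):
            fh.write(f"{arm}\t{g.n_AA}\t{g.n_Aa}\t{g.n_aa}\n")


def _write_variants(path: Path, variants: Sequence[VariantRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tref\talt\tconsequence\tpop_af\tin_segdup\tcarriers\tcadd\n")
        for v in variants:
            af = "" if v.pop_af is None else f"{v.pop_af:g}"
            carriers = ",".join(f"{s}:{gt}" for s, gt in v.carriers)
            cadd = v.annotations.get("cadd", "")
            fh.write(
                f"{v.snp_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.consequence}"
                f"\t{af}\t{int(v.in_segdup)}\t{carriers}\t{cadd}\n"
            )


def emit_fixtures(outdir) -> dict[str, Path]:
    """Write the in-study fixture tables to ``outdir``; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table1_counts": out / "table1_counts.tsv",
        "table3_counts": out / "table3_counts.tsv",
        "table2_variants": out / "table2_variants.tsv",
        "table2_variants_with_decoys": out / "table2_variants_with_decoys.tsv",
        "delta32": out / "delta32_frequencies.tsv",
    }
    _write_counts(paths["table1_counts"], table1_cohort())
    _write_counts(paths["table3_counts"], table3_cohort())
    _write_variants(paths["table2_variants"], table2_variants())
    _write_variants(paths["table2_variants_with_decoys"], table2_variants(include_decoys=True))
    with open(paths["delta32"], "w") as fh:
        fh.write("arm\tallele_freq\tn_individuals\n")
        fh.write(f"cases\t{DELTA32['freq_cases']}\t{DELTA32['n_cases']}\n")
        fh.write(f"controls\t{DELTA32['freq_controls']}\t{DELTA32['n_controls']}\n")
    return paths


# ---------------------------------------------------------------------------
# Whole-locus input bundle for end-to-end runs.

def simulate_locus_inputs(
    cfg: SimConfig,
    outdir,
    gwas_n_cases: int = 2000,
    gwas_n_controls: int = 2000,
    gwas_or: float = 2.0,
    gene_start: int = 46_411_633,
    gene_end: int = 46_417_697,
    gene_name: str = "CCR5",
    tissues: Sequence[str] = ("lung", "liver", "spleen"),
    loop_tissue: str = "lung",
) -> dict:
    """Write a complete synthetic locus: GWAS summary stats from a simulated
    discovery cohort, an eQTL genotype/expression panel, per-tissue contact
    matrices with the loop planted only in ``loop_tissue`` between the causal
    SNP's bin and the gene TSS bin, and a TFBS peak over the causal SNP.

    Returns a dict of file paths plus the locus geometry, suitable for
    feeding straight into :func:`reglocus.pipeline.prioritize`.
    """
    from .assoc import ContingencyTable, association_test, Model
    from .hic import write_contact_matrix

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg, None)

    # --- discovery GWAS on a larger simulated cohort
    gwas_cfg = replace(cfg, n_cases=gwas_n_cases, n_controls=gwas_n_controls, disease_or=gwas_or)
    G, y = simulate_cohort(gwas_cfg, rng)
    sumstats_path = out / "sumstats.tsv"
    with open(sumstats_path, "w") as fh:
        fh.write("SNP\tCHR\tPOS\tREF\tALT\tBETA\tSE\tP\tAF\n")
        for k, spec in enumerate(cfg.snp_panel):
            ca = G[y == 1, k]
            co = G[y == 0, k]
            a, b = int(ca.sum()), int(2 * ca.size - ca.sum())
            c, d = int(co.sum()), int(2 * co.size - co.sum())
            res = association_test(ContingencyTable(a, b, c, d), model=Model.ALLELIC)
            beta = math.log(res.or_)
            se = (math.log(res.ci_high) - math.log(res.or_)) / 1.96
            af = (a + c) / (2.0 * (ca.size + co.size))
            fh.write(
                f"{spec.snp_id}\t{spec.chrom}\t{spec.pos}\t{spec.ref}\t{spec.alt}"
                f"\t{beta:.6g}\t{se:.6g}\t{res.p:.6g}\t{af:.6g}\n"
            )

    # --- eQTL panel
    Ge = simulate_genotypes(cfg, cfg.n_eqtl_samples, rng)
    expr = simulate_expression(Ge, cfg, rng)
    samples = [f"S{i:04d}" for i in range(cfg.n_eqtl_samples)]
    geno_path = out / "genotypes.tsv"
    with open(geno_path, "w") as fh:
        fh.write("sample\t" + "\t".join(cfg.snp_ids) + "\n")
        for s, row in zip(samples, Ge):
            fh.write(s + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    expr_path = out / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("sample\texpression\n")
        for s, v in zip(samples, expr):
            fh.write(f"{s}\t{v:.6g}\n")

    # --- Hi-C per tissue; loop planted only in loop_tissue
    h = cfg.hic
    causal_pos = next(s.pos for s in cfg.snp_panel if s.snp_id == cfg.causal_snp)
    bin_i = (causal_pos - h.start) // h.bin_size
    bin_j = (gene_start - h.start) // h.bin_size
    fold = h.loop[2] if h.loop is not None else 5.0
    matrix_paths = []
    for tissue in tissues:
        loop = (int(bin_i), int(bin_j), fold) if tissue == loop_tissue else None
        mcfg = replace(cfg, hic=replace(h, loop=loop))
        m = simulate_contact_matrix(mcfg, rng, tissue=tissue)
        mpath = out / f"contacts_{tissue}.tsv"
        write_contact_matrix(m, mpath)
        matrix_paths.append(mpath)

    # --- CTCF peak over the causal SNP (BED, 0-based half-open)
    peaks_path = out / "peaks.bed"
    with open(peaks_path, "w") as fh:
        fh.write(f"chr3\t{causal_pos - 500}\t{causal_pos + 500}\tCTCF_synthetic\n")

    region_start = min(s.pos for s in cfg.snp_panel) - 10_000
    region_end = max(s.pos for s in cfg.snp_panel) + 10_000
    return {
        "sumstats": sumstats_path,
        "genotypes": geno_path,
        "expression": expr_path,
        "matrices": matrix_paths,
        "peaks": peaks_path,
        "region": f"chr3:{region_start}-{region_end}",
        "gene": f"chr3:{gene_start}-{gene_end}",
        "gene_name": gene_name,
    }
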