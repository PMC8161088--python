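"""End-to-end prioritization of candidate regulatory SNPs, and the
replication-association report.

``prioritize`` chains the stages: suggestive-significance selection from
GWAS summary statistics -> per-candidate eQTL test against the target gene
-> risk-allele expression-direction call -> per-tissue Hi-C DNIF scoring ->
TFBS peak overlap.  The composite ranking orders candidates by eQTL p-value
ascending, ties by maximal DNIF descending — an explicit, configurable
formalization of the usual narrative procedure, logged in the report
provenance.

``replicate`` renders the five genetic-model association rows (plus per-arm
HWE p-values) from cohort genotype counts — the layout of a classic
replication table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import overlap_snps_peaks, read_peaks_bed
from .assoc import CohortGenotypes, Model, cohort_association
from .eqtl import call_direction, rank_by_eqtl, test_eqtl
from .errors import DegenerateInputError, FormatError, InsufficientDataError
from .hic import read_contact_matrix, snp_gene_dnif
from .popgen import hwe_test
from .sumstats import LocusRegion, read_summary_stats, select_candidates

log = logging.getLogger("reglocus")

__all__ = ["PrioritizationReport", "prioritize", "render_report", "replicate",
           "read_dosage_table", "read_expression_table"]


@dataclass(frozen=True)
class PrioritizationReport:
    rows: pd.DataFrame  # one row per candidate SNP, ranked
    provenance: dict

    @property
    def empty(self) -> bool:
        return self.rows.empty


def read_dosage_table(path) -> pd.DataFrame:
    """Samples x SNPs alt-dosage table; first column names the sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError("duplicate sample ids in dosage table")
    return df


def read_expression_table(path) -> pd.Series:
    """Two-column (sample, value) expression table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise FormatError("expression table must have exactly two columns")
    return df.iloc[:, 0]


def prioritize(config: dict) -> PrioritizationReport:
    """Run the full prioritization; see module docstring for the stages.

    ``config`` keys: sumstats, genotypes, expression, matrices (list),
    peaks, region ('chr:start-end'), gene ('chr:start-end', start = TSS),
    gene_name; optional p_max (1e-5), alpha (0.05), anchor ('tss'),
    columns (sumstats column mapping).
    """
    p_max = float(config.get("p_max", 1e-5))
    alpha = float(config.get("alpha", 0.05))
    anchor = config.get("anchor", "tss")
    gene_name = config.get("gene_name", "gene")
    region = LocusRegion.parse(str(config["region"]))
    gene_region = LocusRegion.parse(str(config["gene"]))

    records = read_summary_stats(config["sumstats"], columns=config.get("columns"))
    log.info("loaded %d summary-statistic records", len(records))
    candidates = select_candidates(records, region, p_max)
    log.info("selected %d candidate SNP(s) at p <= %g in %s", len(candidates), p_max,
             config["region"])

    provenance = {
        "tool": f"reglocus {__version__}",
        "inputs": {
            k: str(config[k])
            for k in ("sumstats", "genotypes", "expression", "peaks")
            if k in config
        },
        "matrices": [str(p) for p in config.get("matrices", [])],
        "region": str(config["region"]),
        "gene": str(config["gene"]),
        "gene_name": gene_name,
        "p_max": p_max,
        "alpha": alpha,
        "anchor": anchor,
        "ranking": "eqtl_p ascending, then max DNIF descending",
        "seed": config.get("seed"),
    }
    if not candidates:
        return PrioritizationReport(rows=pd.DataFrame(), provenance=provenance)

    dosages = read_dosage_table(config["genotypes"])
    expression = read_expression_table(config["expression"]).reindex(dosages.index)
    if expression.isna().any():
        raise FormatError("expression table missing value(s) for genotyped sample(s)")

    eqtls = {}
    for cand in candidates:
        if cand.snp_id not in dosages.columns:
            log.info("no genotypes for %s; skipping eQTL test", cand.snp_id)
            continue
        try:
            eqtls[cand.snp_id] = test_eqtl(
                dosages[cand.snp_id].to_numpy(), expression.to_numpy(),
                gene=gene_name, snp_id=cand.snp_id, ref=cand.ref, alt=cand.alt,
            )
        except (DegenerateInputError, InsufficientDataError) as exc:
            log.info("eQTL test skipped for %s: %s", cand.snp_id, exc)
    log.info("eQTL results for %d of %d candidates", len(eqtls), len(candidates))
    ranking = rank_by_eqtl(candidates, list(eqtls.values()), top_k=len(candidates))

    matrices = [read_contact_matrix(p) for p in config.get("matrices", [])]
    peak_hits = {}
    if config.get("peaks"):
        peaks = read_peaks_bed(config["peaks"])
        peak_hits = overlap_snps_peaks([(c.chrom, c.pos) for c in candidates], peaks)

    rows = []
    for cand in candidates:
        eq = eqtls.get(cand.snp_id)
        direction = call_direction(cand, eq, alpha).direction.value if eq else "indeterminate"
        dnifs = {}
        for m in matrices:
            try:
                r = snp_gene_dnif(m, cand.pos, gene_region.start, gene_region.end, anchor)
                dnifs[m.tissue] = r.dnif
            except IndexError:
                dnifs[m.tissue] = np.nan
        finite = {t: v for t, v in dnifs.items() if np.isfinite(v)}
        top_tissue = min(finite, key=lambda t: (-finite[t], t)) if finite else ""
        rows.append(
            {
                "snp_id": cand.snp_id,
                "chrom": cand.chrom,
                "pos": cand.pos,
                "gwas_p": cand.p,
                "gwas_or": cand.odds_ratio,
                "eqtl_p": eq.p if eq else np.nan,
                "nes": eq.nes if eq else np.nan,
                "direction": direction,
                **{f"dnif_{t}": v for t, v in dnifs.items()},
                "max_dnif": max(finite.values()) if finite else np.nan,
                "top_tissue": top_tissue,
                "tfbs": ";".join(peak_hits.get((cand.chrom, cand.pos), [])),
            }
        )
    df = pd.DataFrame(rows)
    order = np.lexsort(
        (
            df["snp_id"].to_numpy(),
            -np.nan_to_num(df["max_dnif"].to_numpy(), nan=-np.inf),
            np.nan_to_num(df["eqtl_p"].to_numpy(), nan=np.inf),
        )
    )
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    # consistency with the significance ranking on SNPs that have eQTLs
    assert [s for s, _ in ranking] == [
        s for s in df.loc[df["eqtl_p"].notna()].sort_values(["eqtl_p", "snp_id"])["snp_id"]
    ]
    return PrioritizationReport(rows=df, provenance=provenance)


def render_report(report: PrioritizationReport) -> str:
    """Provenance header ('#'-prefixed) followed by the tab-delimited body."""
    lines = [f"# {k}: {v}" for k, v in report.provenance.items()]
    body = report.rows.to_csv(sep="\t", index=False, float_format="%.6g")
    return "\n".join(lines) + "\n" + body


@dataclass(frozen=True)
class ReplicationReport:
    models: pd.DataFrame
    hwe_case_p: float
    hwe_control_p: float


_MODEL_LABEL = {
    Model.CODOMINANT_HET: "het vs major-hom",
    Model.CODOMINANT_HOM: "minor-hom vs major-hom",
    Model.ALLELIC: "minor vs major allele",
    Model.DOMINANT_CARRIER: "carriers vs major-hom",
    Model.RECESSIVE_HOM: "minor-hom vs rest",
}


def replicate(cohort: CohortGenotypes, test: str = "pearson_chi2") -> ReplicationReport:
    """Five genetic-model association rows plus per-arm HWE p-values."""
    results = cohort_association(cohort, test=test)
    rows = []
    for model, res in results.items():
        t = res.table
        rows.append(
            {
                "model": model.value,
                "comparison": _MODEL_LABEL[model],
                "cases_exposed": t.a,
                "cases_unexposed": t.b,
                "controls_exposed": t.c,
                "controls_unexposed": t.d,
                "cases_pct": round(100.0 * t.a / (t.a + t.b), 1),
                "controls_pct": round(100.0 * t.c / (t.c + t.d), 1),
                "OR": round(res.or_, 3),
                "ci_low": round(res.ci_low, 3),
                "ci_high": round(res.ci_high, 3),
                "p": float(f"{res.p:.3g}"),
                "test": res.test,
                "corrected": res.corrected,
            }
        )
    try:
        _, hwe_ca = hwe_test(cohort.case_counts)
        _, hwe_co = hwe_test(cohort.control_counts)
    except DegenerateInputError:
        hwe_ca = hwe_co = float("nan")
    return ReplicationReport(models=pd.DataFrame(rows), hwe_case_p=hwe_ca, hwe_control_p=hwe_co)
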