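"""Full study-style analysis report: orchestration and writers.

Runs the pedigree pipeline (validation -> founders/completeness/matings/
litters -> kinship/inbreeding/Ne -> gene drop) and, when genotypes are
supplied, the marker pipeline (per-locus diversity statistics and the MCMC
exact HWE test), and assembles everything into one JSON-serialisable report
with a provenance block (input hashes, seeds, settings, version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .genedrop import GeneDropConfig, run_gene_drop
from .genotypes import read_genotypes
from .kinship import (average_relatedness, delta_F_and_Ne, demographic_ne,
                      inbreeding_by_year, inbreeding_coefficients,
                      kinship_matrix, mean_kinship_summary)
from .pedigree import (classify_matings, completeness, generation_interval,
                       identify_founders, litter_statistics,
                       progeny_statistics, read_pedigree, PedigreeError)
from .strstats import panel_summary

__all__ = ["AnalysisReport", "run_full_analysis"]


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.reset_index().to_dict(orient="records")
    return obj


@dataclass
class AnalysisReport:
    """Assembled pipeline output plus provenance."""

    pedigree: dict
    diversity: dict
    gene_drop: dict | None
    markers: dict | None
    provenance: dict
    tables: dict = field(default_factory=dict, repr=False)

    def to_json(self, indent: int = 2) -> str:
        payload = {"pedigree": self.pedigree, "diversity": self.diversity,
                   "gene_drop": self.gene_drop, "markers": self.markers,
                   "provenance": self.provenance}
        return json.dumps(_jsonable(payload), indent=indent, sort_keys=True)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json() + "\n")
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.6g")


def _f_distribution_bins(F: np.ndarray, width: float = 0.05) -> pd.DataFrame:
    """Inbreeding-coefficient histogram bins (percent scale)."""
    edges = np.arange(0.0, max(0.30001, F.max() + width), width)
    counts, _ = np.histogram(F, bins=edges)
    return pd.DataFrame({
        "F_low_pct": 100 * edges[:-1], "F_high_pct": 100 * edges[1:],
        "n": counts})


def run_full_analysis(pedigree_path, genotype_path=None,
                      genotype_format: str = "genepop",
                      census_n: int | None = None, seed: int = 0,
                      genedrop_replicates: int = 10_000,
                      genedrop_cohort: list[str] | None = None,
                      hwe_settings: dict | None = None,
                      outdir=None) -> AnalysisReport:
    """Execute the complete pipeline and optionally write JSON + TSV output.

    ``hwe_settings`` defaults to the study chain settings (100 batches,
    10,000 dememorization steps, 5,000 iterations per batch).
    """
    ped = read_pedigree(pedigree_path)
    founders = identify_founders(ped)
    comp = completeness(ped)
    matings = classify_matings(ped)
    litters = litter_statistics(ped)
    progeny = progeny_statistics(ped, founders)
    try:
        interval = generation_interval(ped)
    except PedigreeError:
        interval = None

    kin = kinship_matrix(ped)
    inb = inbreeding_coefficients(ped, kin)
    ar = average_relatedness(ped, kin)
    mks = mean_kinship_summary(kin)
    try:
        ne = delta_F_and_Ne(ped, census_n=census_n, kin=kin)
    except PedigreeError:
        ne = None
    by_year = inbreeding_by_year(ped, kin)

    drop = run_gene_drop(ped, GeneDropConfig(replicates=genedrop_replicates,
                                             cohort=genedrop_cohort, seed=seed))

    pedigree_block = {
        "n_records": len(ped),
        "founders": {"any_unknown": founders.n_any_unknown,
                     "both_unknown": founders.n_both_unknown,
                     "without_progeny": founders.founders_without_progeny,
                     "breeding_use_fraction": founders.breeding_use_fraction},
        "completeness": {"mean_max_generations": comp.mean_max_generations,
                         "mean_complete_generations": comp.mean_complete_generations,
                         "mean_equivalent_complete_generations":
                             comp.mean_equivalent_complete_generations},
        "matings": matings.as_dict(),
        "litters": {"litter": litters.litter_stats,
                    "full_sib_group": litters.full_sib_group_stats,
                    "n_full_sib_groups": litters.n_full_sib_groups,
                    "n_individuals_in_full_sib_groups":
                        litters.n_individuals_in_full_sib_groups},
        "generation_interval": interval,
        "breeding": {"n_breeders": progeny.n_breeders,
                     "n_breeder_males": progeny.n_breeder_males,
                     "n_breeder_females": progeny.n_breeder_females,
                     "n_zero_progeny": progeny.n_zero_progeny},
    }
    diversity_block = {
        "mean_F": inb.mean, "sd_F": inb.sd, "n_inbred": inb.n_inbred,
        "n_F_above_20pct": inb.n_above_20pct, "n_F_above_25pct": inb.n_above_25pct,
        "mean_AR": ar["mean"], "n_AR_above_25pct": ar["n_above_25pct"],
        "MK": mks["MK"], "GD": mks["GD"], "fge": mks["fge"],
        "delta_F": None if ne is None else ne["delta_F"],
        "Ne": None if ne is None else ne["Ne"],
        "Ne_demographic": None if ne is None else ne["Ne_demographic"],
        "Ne_over_N": None if ne is None or not census_n else ne["Ne"] / census_n,
        "census_n": census_n,
    }
    drop_block = {"fgs": drop.fgs, "fgs_se": drop.fgs_se,
                  "replicates": genedrop_replicates,
                  "n_founder_genomes_scored": len(drop.founder_ids)}

    markers_block = None
    tables = {
        "inbreeding_by_year": by_year,
        "f_distribution": _f_distribution_bins(inb.values.to_numpy()),
        "per_individual": pd.DataFrame({
            "id": ped.ids, "F": inb.values.to_numpy(),
            "AR": ar["values"].to_numpy(),
            "t": comp.equivalent_complete_generations}),
    }
    if genotype_path is not None:
        geno = read_genotypes(genotype_path, format=genotype_format)
        settings = hwe_settings if hwe_settings is not None else {
            "batches": 100, "dememorization": 10_000,
            "iters_per_batch": 5_000, "seed": seed}
        summary = panel_summary(geno, hwe=settings)
        markers_block = {
            "n_individuals": geno.n_individuals,
            "n_loci": len(geno.loci),
            "total_alleles": summary.total_alleles,
            "mean_PIC": summary.mean("pic"), "mean_Ho": summary.mean("ho"),
            "mean_He": summary.mean("he"), "mean_FIS": summary.mean("fis"),
            "hwe_settings": settings,
        }
        tables["marker_table"] = summary.as_frame().reset_index()

    provenance = {
        "tool": "pedvar", "version": _version, "seed": seed,
        "pedigree_file": str(pedigree_path), "pedigree_sha256": _sha256(pedigree_path),
        "genotype_file": None if genotype_path is None else str(genotype_path),
        "genotype_sha256": None if genotype_path is None else _sha256(genotype_path),
        "settings": {"census_n": census_n,
                     "genedrop_replicates": genedrop_replicates},
    }
    report = AnalysisReport(pedigree=pedigree_block, diversity=diversity_block,
                            gene_drop=drop_block, markers=markers_block,
                            provenance=provenance, tables=tables)
    if outdir is not None:
        report.write(outdir)
    return report
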