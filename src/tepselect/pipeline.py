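"""End-to-end pipeline orchestration.

Runs identification filtering, binder annotation, HPV calling,
comparative profiling, cohort statistics, warehouse optimisation and
per-patient composition in order, writing each stage's outputs and a run
manifest (thresholds, seed, per-stage record counters, assumption flags)
to the output directory. Deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import binding, hpv, profiling, stats, tables, warehouse
from .hla import parse_allele
from .records import PatientGenotype, apply_identification_filters, ligandomes_from_records

logger = logging.getLogger(__name__)

#: Methodological choices surfaced in every manifest.
ASSUMPTION_FLAGS = {
    "hpv_sum_branch": "per HPV type (not summed across types)",
    "binder_rule": "OR across per-allele motifs; assignment = best-scoring passing motif",
    "exclusivity_matching": "exact peptide sequence within HLA class; I/L kept distinct",
    "saturation_model": "S_max*(1-exp(-k*n)) least-squares fit of the accumulation curve",
    "selection_rule": "smallest selection attaining maximal attainable coverage",
    "allotype_skip_rule": "skip allotypes whose optimal selection covers <=1 carrier",
}


@dataclass
class PipelineConfig:
    peptide_table: str
    hla_typing: str
    benign_reference: str
    oncogene_counts: Optional[str] = None
    binder_calls: Optional[str] = None
    motif_table: Optional[str] = None
    masses: Optional[str] = None  # TSV [patient_id, tissue_mass_mg]
    query_fasta: Optional[str] = None
    out_dir: str = "tepselect_out"
    q_max: float = 0.05
    len_min: int = 8
    len_max: int = 25
    qc_min_psm: int = warehouse.QC_MIN_PSM
    qc_min_xcorr: float = warehouse.QC_MIN_XCORR
    qc_min_delta_cn: float = warehouse.QC_MIN_DELTA_CN
    hpv_threshold: int = 500
    min_patients_i: int = 2
    min_patients_ii: int = 3
    top_n_per_isotype: int = 5
    iterations: int = 1_000_000
    max_runs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_max", "len_min", "len_max", "qc_min_psm", "qc_min_xcorr",
                     "qc_min_delta_cn", "hpv_threshold", "min_patients_i",
                     "min_patients_ii", "iterations", "max_runs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> tuple[int, dict]:
    """Execute all stages; returns (exit status, manifest).

    On a stage error the manifest marks the failure point, partial
    outputs are preserved, and the exit status is non-zero.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in ("q_max", "len_min", "len_max", "qc_min_psm", "qc_min_xcorr",
                      "qc_min_delta_cn", "hpv_threshold", "min_patients_i",
                      "min_patients_ii", "iterations", "max_runs")
        },
        "assumptions": ASSUMPTION_FLAGS,
        "stages": [],
    }

    def stage(name: str):
        entry = {"name": name, "status": "running", "counters": {}}
        manifest["stages"].append(entry)
        return entry

    def finish(status: int) -> tuple[int, dict]:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return status, manifest

    try:
        # 1. identification filtering -----------------------------------
        st = stage("filter")
        records = tables.read_peptide_table(config.peptide_table)
        st["counters"]["records_in"] = len(records)
        records = apply_identification_filters(
            records, config.q_max, config.len_min, config.len_max
        )
        st["counters"]["records_out"] = len(records)
        tables.write_peptide_table(records, out / "filtered_peptides.tsv")
        typing = tables.read_hla_typing(config.hla_typing)
        genotypes = [
            PatientGenotype(patient_id=pid, alleles=tuple(alleles))
            for pid, alleles in sorted(typing.items())
        ]
        st["status"] = "completed"

        # 2. binder annotation ------------------------------------------
        st = stage("binder_annotation")
        ligandomes = ligandomes_from_records(records)
        if config.motif_table:
            motifs = binding.read_motif_table(config.motif_table)
            geno_by_id = {g.patient_id: g for g in genotypes}
            ligandomes = {
                sid: binding.annotate_binders(lig, geno_by_id[sid], motifs)
                if sid in geno_by_id
                else lig
                for sid, lig in ligandomes.items()
            }
        elif config.binder_calls:
            calls = tables.read_binder_calls(config.binder_calls)
            for lig in ligandomes.values():
                lig.binder_flags = {
                    p: calls.get(p, (False, None))[0] for p in lig.class_i_peptides
                }
                lig.allele_assignments = {
                    p: calls[p][1]
                    for p in lig.class_i_peptides
                    if calls.get(p, (False, None))[1] is not None
                }
        st["counters"]["samples"] = len(ligandomes)
        st["counters"]["mean_purity"] = round(
            float(pd.Series([l.purity for l in ligandomes.values()]).mean()), 4
        ) if ligandomes else None
        st["status"] = "completed"

        # 3. HPV calling -------------------------------------------------
        st = stage("hpv_calling")
        hpv_calls: dict[str, hpv.HPVCall] = {}
        if config.oncogene_counts:
            counts = tables.read_oncogene_counts(config.oncogene_counts)
            hpv_calls = hpv.call_cohort(counts, config.hpv_threshold)
            pd.DataFrame(
                [
                    {
                        "patient_id": c.patient_id,
                        "status": c.status,
                        "hpv_type": c.hpv_type or "",
                        "total_oncogene_reads": c.total_oncogene_reads,
                    }
                    for c in hpv_calls.values()
                ]
            ).to_csv(out / "hpv_calls.tsv", sep="\t", index=False)
            genotypes = [
                PatientGenotype(
                    patient_id=g.patient_id,
                    alleles=g.alleles,
                    hpv_status=hpv_calls[g.patient_id].status
                    if g.patient_id in hpv_calls
                    else "unknown",
                    hpv_type=hpv_calls[g.patient_id].hpv_type
                    if g.patient_id in hpv_calls
                    else None,
                    metadata=g.metadata,
                    tissue_mass_mg=g.tissue_mass_mg,
                )
                for g in genotypes
            ]
        st["counters"]["n_positive"] = sum(
            1 for c in hpv_calls.values() if c.status == "positive"
        )
        st["status"] = "completed"

        # 4. comparative profiling --------------------------------------
        st = stage("profiling")
        benign = tables.read_benign_reference(config.benign_reference)
        ligs = [ligandomes[k] for k in sorted(ligandomes)]
        teps = {}
        for cls in ("I", "II"):
            t = profiling.identify_tep(ligs, benign, cls) if ligs else []
            if hpv_calls and ligs:
                strata = profiling.stratify_by_hpv(ligs, hpv_calls, cls)
                t = profiling.annotate_hpv_strata(t, strata)
            teps[cls] = t
            pd.DataFrame(
                [
                    {
                        "sequence": x.sequence,
                        "hla_class": x.hla_class,
                        "n_samples": x.n_positive_samples,
                        "prevalence_pct": x.prevalence_pct,
                        "hpv_stratum": x.hpv_stratum or "",
                    }
                    for x in t
                ]
            ).to_csv(out / f"tep_class_{cls.lower()}.tsv", sep="\t", index=False)
            st["counters"][f"n_tep_class_{cls}"] = len(t)
        length_json = {
            cls: profiling.length_distribution(ligs, cls)
            for cls in ("I", "II")
            if any(lig.peptides(cls) for lig in ligs)
        }
        with open(out / "length_distributions.json", "w") as fh:
            json.dump(length_json, fh, indent=2)
        st["status"] = "completed"

        # 5. cohort statistics ------------------------------------------
        st = stage("stats")
        stats.cohort_summary(genotypes).to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
        if config.masses:
            mass_df = pd.read_csv(config.masses, sep="\t")
            yields = {
                sid: len(lig.ligands()) for sid, lig in ligandomes.items()
            }
            pairs = [
                (row.tissue_mass_mg, yields[str(row.patient_id)])
                for row in mass_df.itertuples(index=False)
                if str(row.patient_id) in yields
            ]
            if len(pairs) >= 3:
                r, ci, p = stats.mass_yield_correlation(pairs)
                with open(out / "mass_yield.json", "w") as fh:
                    json.dump({"r": r, "ci": list(ci), "p": p, "n": len(pairs)}, fh, indent=2)
                st["counters"]["mass_yield_r"] = round(r, 4)
        st["status"] = "completed"

        # 6. warehouse ---------------------------------------------------
        st = stage("warehouse")
        qc_pass, qc_fail = warehouse.qc_filter(
            records, config.qc_min_psm, config.qc_min_xcorr, config.qc_min_delta_cn
        )
        st["counters"]["qc_pass"] = len(qc_pass)
        st["counters"]["qc_fail"] = len(qc_fail)
        carrier_counts: dict = {}
        for g in genotypes:
            for a in set(g.class_i_alleles):
                carrier_counts[a] = carrier_counts.get(a, 0) + 1
        top_allotypes = []
        for locus in ("A", "B", "C"):
            locus_alleles = sorted(
                (a for a in carrier_counts if a.locus == locus),
                key=lambda a: (-carrier_counts[a], a.render()),
            )
            top_allotypes.extend(locus_alleles[: config.top_n_per_isotype])
        selections = []
        skipped = []
        for allotype in top_allotypes:
            matrix = warehouse.build_incidence(
                allotype, ligandomes, genotypes, teps["I"], config.min_patients_i
            )
            sel = warehouse.optimise_with_qc(
                matrix, qc_pass, config.max_runs, config.iterations, config.seed
            )
            if len(sel.covered_patients) <= 1:
                skipped.append(allotype.render())
                continue
            selections.append(sel)
        sel_ii = warehouse.select_class_ii(
            teps["II"], ligandomes, qc_pass, config.min_patients_ii,
            hpv_calls or None, config.iterations, config.seed,
        )
        wh_json = {
            "class_i": [
                {
                    "allotype": s.allotype.render(),
                    "selected": s.selected,
                    "coverage_pct": s.coverage_pct,
                    "pareto_front": s.pareto_front,
                    "n_runs": s.n_runs,
                    "qc_removed": s.qc_removed,
                    "method": s.method,
                }
                for s in selections
            ],
            "class_ii": {
                "selected": sel_ii.selected,
                "coverage_pct": sel_ii.coverage_pct,
                "coverage_by_status": sel_ii.coverage_by_status,
                "pareto_front": sel_ii.pareto_front,
            },
            "skipped_allotypes": skipped,
        }
        with open(out / "warehouse.json", "w") as fh:
            json.dump(wh_json, fh, indent=2)
        st["counters"]["n_allotypes_selected"] = len(selections)
        st["counters"]["n_allotypes_skipped"] = len(skipped)
        st["counters"]["n_peptides_class_i"] = sum(len(s.selected) for s in selections)
        st["counters"]["n_peptides_class_ii"] = len(sel_ii.selected)
        st["status"] = "completed"

        # 7. patient compositions ---------------------------------------
        st = stage("compositions")
        report = warehouse.coverage_report(selections, genotypes, ligandomes)
        report.per_patient.to_csv(out / "patient_compositions.tsv", sep="\t", index=False)
        report.per_allotype.to_csv(out / "allotype_coverage.tsv", sep="\t", index=False)
        with open(out / "composition_summary.json", "w") as fh:
            json.dump(report.summary, fh, indent=2)
        st["counters"].update({k: v for k, v in report.summary.items() if not isinstance(v, list)})
        st["status"] = "completed"

        manifest["status"] = "completed"
        return finish(0)
    except Exception as exc:  # stage failure: preserve partial outputs
        logger.exception("pipeline stage failed")
        if manifest["stages"]:
            manifest["stages"][-1]["status"] = "failed"
            manifest["stages"][-1]["error"] = str(exc)
        manifest["status"] = "failed"
        return finish(1)


def write_cohort(cohort, out_dir) -> None:
    """Write a :class:`~tepselect.simulate.SimulatedCohort` to the tabular
    interchange formats (peptide records, typing, benign reference,
    oncogene counts, masses)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables.write_peptide_table(cohort.records, out / "peptides.tsv")
    tables.write_hla_typing(cohort.genotypes, out / "hla_typing.tsv")
    tables.write_benign_reference(cohort.benign, out / "benign_reference.tsv")
    tables.write_oncogene_counts(cohort.oncogene_counts, out / "oncogene_counts.tsv")
    pd.DataFrame(
        [
            {"patient_id": g.patient_id, "tissue_mass_mg": g.tissue_mass_mg}
            for g in cohort.genotypes
        ]
    ).to_csv(out / "masses.tsv", sep="\t", index=False)
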