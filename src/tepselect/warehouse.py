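"""Peptide warehouse construction.

For each frequent HLA class I allotype, tumour-exclusive peptides (TEP)
presented by at least two carriers form an incidence matrix
(peptides × carrier patients). A bi-objective optimisation — maximise
carrier coverage, minimise the number of peptides — yields a Pareto
front; the reported selection is the smallest set attaining the maximal
attainable coverage. Peptides entering a selection must pass spectral
quality control (PSM count ≥ 2, Xcorr ≥ 1.5, ΔCn ≥ 0.2); when a selected
peptide fails QC it is removed from the candidate pool and the
optimisation re-runs, up to three runs in total. Class II TEP are
optimised once over the whole cohort, allotype-agnostically. Per
patient, the union of the selections for the allotypes they carry forms
a semi-personalised composition.

Instances with at most 20 candidate peptides are solved exactly by
subset enumeration; larger instances use a greedy-seeded, seeded
stochastic local search with a fixed iteration budget (default 10^6).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .hla import HLAAllele
from .records import Ligandome, PatientGenotype, PeptideRecord
from .profiling import TEPRecord

logger = logging.getLogger(__name__)

__all__ = [
    "QC_MIN_PSM",
    "QC_MIN_XCORR",
    "QC_MIN_DELTA_CN",
    "qc_filter",
    "IncidenceMatrix",
    "WarehouseSelection",
    "PatientComposition",
    "build_incidence",
    "optimise_selection",
    "optimise_with_qc",
    "select_class_ii",
    "compose_patient",
    "coverage_report",
    "EXHAUSTIVE_LIMIT",
]

# Spectral quality gates for warehouse candidates; boundaries inclusive.
QC_MIN_PSM = 2
QC_MIN_XCORR = 1.5
QC_MIN_DELTA_CN = 0.2

#: Largest candidate count solved by exhaustive subset enumeration.
EXHAUSTIVE_LIMIT = 20


def qc_filter(
    records: Iterable[PeptideRecord],
    min_psm: int = QC_MIN_PSM,
    min_xcorr: float = QC_MIN_XCORR,
    min_delta_cn: float = QC_MIN_DELTA_CN,
) -> tuple[set[str], set[str]]:
    """Split peptides into QC pass / fail sets.

    Metrics are aggregated across samples: a peptide passes when its best
    PSM count, best Xcorr and best ΔCn each reach the (inclusive) gate.
    A peptide with a missing (NaN) metric fails.
    """
    best: dict[str, list[float]] = {}
    for r in records:
        m = best.setdefault(r.sequence, [-math.inf, -math.inf, -math.inf])
        m[0] = max(m[0], r.psm_count)
        m[1] = max(m[1], r.xcorr if not math.isnan(r.xcorr) else -math.inf)
        m[2] = max(m[2], r.delta_cn if not math.isnan(r.delta_cn) else -math.inf)
    passed = {
        seq
        for seq, (psm, xc, dcn) in best.items()
        if psm >= min_psm and xc >= min_xcorr and dcn >= min_delta_cn
    }
    return passed, set(best) - passed


@dataclass
class IncidenceMatrix:
    """Peptide × carrier-patient presence matrix for one allotype."""

    allotype: Optional[HLAAllele]
    peptides: list[str]
    patients: list[str]
    present: np.ndarray  # bool, shape (len(peptides), len(patients))

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.peptides), len(self.patients)):
            raise ValueError("incidence shape does not match peptide/patient lists")
        if len(self.peptides) and not self.present.any(axis=1).all():
            raise ValueError("every peptide row must cover at least one patient")

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def masks(self) -> list[int]:
        """Per-peptide patient-coverage bitmasks."""
        return [
            int(sum(1 << j for j in np.flatnonzero(self.present[i])))
            for i in range(self.n_peptides)
        ]


@dataclass
class WarehouseSelection:
    """Optimisation outcome for one allotype (or the class II pool)."""

    allotype: Optional[HLAAllele]
    selected: list[str]
    covered_patients: set[str]
    coverage_pct: float
    pareto_front: list[tuple[int, int]]  # (selection size, carriers covered)
    n_runs: int = 1
    qc_removed: list[str] = field(default_factory=list)
    candidates_seen: list[str] = field(default_factory=list)
    method: str = "exhaustive"
    coverage_by_status: Optional[dict[str, float]] = None


@dataclass
class PatientComposition:
    """Semi-personalised warehouse selection for one patient."""

    patient_id: str
    selected_teps: set[str]
    presented_teps: set[str]
    pct_of_selected: float

    def __post_init__(self) -> None:
        if not self.presented_teps <= self.selected_teps:
            raise ValueError("presented peptides must be a subset of selected peptides")


def build_incidence(
    allotype: HLAAllele,
    ligandomes: Mapping[str, Ligandome],
    genotypes: Sequence[PatientGenotype],
    teps: Iterable[TEPRecord],
    min_patients: int = 2,
) -> IncidenceMatrix:
    """Candidate incidence matrix for one class I allotype.

    Rows are TEP assigned to `allotype` (by binder annotation in at least
    one carrier sample) and presented by at least `min_patients` carriers;
    columns are the carrier patients. A cell is true when the carrier's
    ligandome presents the peptide as a binder.
    """
    carriers = [g.patient_id for g in genotypes if allotype in g.class_i_alleles]
    if not carriers:
        raise ValueError(f"no carriers of {allotype.render()} in the cohort")
    carrier_ligs = [ligandomes.get(pid) for pid in carriers]

    rows: list[str] = []
    cells: list[list[bool]] = []
    for t in sorted({t.sequence for t in teps}):
        assigned = any(
            lig is not None and lig.allele_assignments.get(t) == allotype
            for lig in carrier_ligs
        )
        if not assigned:
            continue
        presence = [lig is not None and t in lig.ligands() for lig in carrier_ligs]
        if sum(presence) >= min_patients:
            rows.append(t)
            cells.append(presence)
    present = np.array(cells, dtype=bool) if rows else np.zeros((0, len(carriers)), dtype=bool)
    return IncidenceMatrix(allotype=allotype, peptides=rows, patients=carriers, present=present)


def _pareto_from_best(best_cov_by_size: Sequence[int]) -> list[tuple[int, int]]:
    """Non-dominated (size, coverage) points from best coverage per size."""
    front: list[tuple[int, int]] = []
    prev = 0
    for size in range(1, len(best_cov_by_size)):
        cov = best_cov_by_size[size]
        if cov > prev:
            front.append((size, cov))
            prev = cov
    return front


def _exhaustive(masks: list[int], n_patients: int) -> tuple[list[tuple[int, int]], int, int]:
    """Best coverage per size by dynamic programming over all subsets.

    Returns (pareto front, max coverage, minimal size attaining it).
    """
    n = len(masks)
    cover = [0] * (1 << n)
    for s in range(1, 1 << n):
        low = s & -s
        cover[s] = cover[s ^ low] | masks[low.bit_length() - 1]
    best = [0] * (n + 1)
    for s in range(1 << n):
        size = s.bit_count()
        c = cover[s].bit_count()
        if c > best[size]:
            best[size] = c
    # larger selections can never cover fewer patients
    for size in range(1, n + 1):
        best[size] = max(best[size], best[size - 1])
    max_cov = best[n]
    k_star = next(size for size in range(n + 1) if best[size] == max_cov)
    return _pareto_from_best(best), max_cov, k_star


def _lex_smallest_of_size(
    peptides: list[str], masks: list[int], k: int, target_cov: int
) -> list[int]:
    """First size-`k` combination (in lexicographic peptide order) with
    coverage `target_cov`. `peptides` must already be sorted."""
    if k == 0:
        return []
    for combo in itertools.combinations(range(len(peptides)), k):
        m = 0
        for i in combo:
            m |= masks[i]
        if m.bit_count() == target_cov:
            return list(combo)
    raise AssertionError("no combination attains the computed optimum")  # pragma: no cover


def _greedy(masks: list[int]) -> list[int]:
    """Greedy max-marginal-coverage chain; ties by peptide order (lex)."""
    chosen: list[int] = []
    covered = 0
    remaining = list(range(len(masks)))
    while remaining:
        gains = [(-(masks[i] | covered).bit_count(), i) for i in remaining]
        gains.sort()
        best_gain, best_i = gains[0]
        if -best_gain == covered.bit_count():
            break
        chosen.append(best_i)
        covered |= masks[best_i]
        remaining.remove(best_i)
    return chosen


def _stochastic(
    masks: list[int], iterations: int, seed: int
) -> tuple[list[tuple[int, int]], int, int, list[int]]:
    """Greedy-seeded local search under a fixed move budget.

    Tracks the best coverage attained at every selection size and the
    best (smallest, lexicographically first) selection achieving the
    best coverage seen.
    """
    n = len(masks)
    rng = np.random.default_rng(seed)
    best_by_size = [0] * (n + 1)

    def record(sel: set[int]) -> int:
        m = 0
        for i in sel:
            m |= masks[i]
        c = m.bit_count()
        k = len(sel)
        if c > best_by_size[k]:
            best_by_size[k] = c
        return c

    greedy_sel = _greedy(masks)
    current = set(greedy_sel)
    for j in range(1, len(greedy_sel) + 1):
        record(set(greedy_sel[:j]))
    best_sel = sorted(current)
    best_key = (-record(current), len(current), best_sel)

    for _ in range(int(iterations)):
        move = rng.integers(0, 3)
        cand = set(current)
        if move == 0 and len(cand) < n:  # add
            options = [i for i in range(n) if i not in cand]
            cand.add(options[rng.integers(0, len(options))])
        elif move == 1 and cand:  # drop
            cand.remove(sorted(cand)[rng.integers(0, len(cand))])
        elif move == 2 and cand and len(cand) < n:  # swap
            options = [i for i in range(n) if i not in cand]
            cand.remove(sorted(cand)[rng.integers(0, len(cand))])
            cand.add(options[rng.integers(0, len(options))])
        else:
            continue
        c = record(cand)
        key = (-c, len(cand), sorted(cand))
        if key <= best_key:
            best_key = key
            best_sel = sorted(cand)
            current = cand
    # monotonise best-by-size and derive the front
    for size in range(1, n + 1):
        best_by_size[size] = max(best_by_size[size], best_by_size[size - 1])
    max_cov = -best_key[0]
    return _pareto_from_best(best_by_size), max_cov, len(best_sel), best_sel


def optimise_selection(
    matrix: IncidenceMatrix,
    iterations: int = 1_000_000,
    seed: int = 0,
) -> WarehouseSelection:
    """Bi-objective (coverage max, size min) peptide selection.

    Exact subset enumeration when the candidate pool has at most
    :data:`EXHAUSTIVE_LIMIT` peptides; otherwise greedy-seeded stochastic
    local search with `iterations` moves driven by `seed`. The reported
    selection is the smallest set attaining the maximal attainable
    coverage; ties are broken by the lexicographically smallest peptide
    list.
    """
    if matrix.n_peptides == 0:
        return WarehouseSelection(
            allotype=matrix.allotype,
            selected=[],
            covered_patients=set(),
            coverage_pct=0.0,
            pareto_front=[],
            method="empty",
        )
    order = sorted(range(matrix.n_peptides), key=lambda i: matrix.peptides[i])
    peptides = [matrix.peptides[i] for i in order]
    all_masks = matrix.masks()
    masks = [all_masks[i] for i in order]

    if matrix.n_peptides <= EXHAUSTIVE_LIMIT:
        front, max_cov, k_star = _exhaustive(masks, matrix.n_patients)
        idx = _lex_smallest_of_size(peptides, masks, k_star, max_cov)
        method = "exhaustive"
    else:
        front, max_cov, k_star, idx = _stochastic(masks, iterations, seed)
        method = "stochastic"

    covered_mask = 0
    for i in idx:
        covered_mask |= masks[i]
    covered = {matrix.patients[j] for j in range(matrix.n_patients) if covered_mask >> j & 1}
    return WarehouseSelection(
        allotype=matrix.allotype,
        selected=[peptides[i] for i in idx],
        covered_patients=covered,
        coverage_pct=100.0 * len(covered) / matrix.n_patients if matrix.n_patients else 0.0,
        pareto_front=front,
        candidates_seen=[peptides[i] for i in idx],
        method=method,
    )


def _submatrix(matrix: IncidenceMatrix, keep: Sequence[str]) -> IncidenceMatrix:
    idx = [i for i, p in enumerate(matrix.peptides) if p in set(keep)]
    return IncidenceMatrix(
        allotype=matrix.allotype,
        peptides=[matrix.peptides[i] for i in idx],
        patients=list(matrix.patients),
        present=matrix.present[idx] if idx else np.zeros((0, matrix.n_patients), dtype=bool),
    )


def optimise_with_qc(
    matrix: IncidenceMatrix,
    qc_pass: set[str],
    max_runs: int = 3,
    iterations: int = 1_000_000,
    seed: int = 0,
) -> WarehouseSelection:
    """Optimise with post-hoc QC and re-runs.

    The optimisation runs on the full candidate pool; any selected
    peptide failing QC is removed from the pool and the optimisation
    re-runs, up to `max_runs` runs in total. Every peptide that appeared
    in any run's selection is recorded as a warehouse candidate. Should
    QC failures survive the final run they are dropped from the reported
    selection, so the output is always QC-clean.
    """
    pool = list(matrix.peptides)
    qc_removed: list[str] = []
    candidates: list[str] = []
    n_runs = 0
    sel = optimise_selection(_submatrix(matrix, pool), iterations, seed)
    while True:
        n_runs += 1
        candidates.extend(p for p in sel.selected if p not in candidates)
        failing = [p for p in sel.selected if p not in qc_pass]
        if not failing or n_runs >= max_runs:
            break
        qc_removed.extend(failing)
        pool = [p for p in pool if p not in set(failing)]
        sel = optimise_selection(_submatrix(matrix, pool), iterations, seed)

    final = [p for p in sel.selected if p in qc_pass]
    if len(final) != len(sel.selected):
        qc_removed.extend(p for p in sel.selected if p not in qc_pass)
        mask_patients: set[str] = set()
        for p in final:
            i = matrix.peptides.index(p)
            mask_patients |= {
                matrix.patients[j] for j in np.flatnonzero(matrix.present[i])
            }
        covered = mask_patients
    else:
        covered = sel.covered_patients
    return WarehouseSelection(
        allotype=matrix.allotype,
        selected=final,
        covered_patients=covered,
        coverage_pct=100.0 * len(covered) / matrix.n_patients if matrix.n_patients else 0.0,
        pareto_front=sel.pareto_front,
        n_runs=n_runs,
        qc_removed=qc_removed,
        candidates_seen=candidates,
        method=sel.method,
    )


def select_class_ii(
    teps_class_ii: Iterable[TEPRecord],
    ligandomes: Mapping[str, Ligandome],
    qc_pass: set[str],
    min_patients: int = 3,
    hpv_calls: Optional[Mapping[str, object]] = None,
    iterations: int = 1_000_000,
    seed: int = 0,
) -> WarehouseSelection:
    """Allotype-agnostic class II selection over the whole cohort.

    Candidates are class II TEP found in at least `min_patients`
    ligandomes that pass QC (QC here eliminates candidates up front).
    Coverage is reported over all patients, and additionally by HPV
    status when calls are supplied.
    """
    patients = sorted(ligandomes)
    candidates = sorted(
        t.sequence
        for t in teps_class_ii
        if t.n_positive_samples >= min_patients and t.sequence in qc_pass
    )
    cells = [
        [seq in ligandomes[pid].class_ii_peptides for pid in patients]
        for seq in candidates
    ]
    keep = [i for i, row in enumerate(cells) if any(row)]
    matrix = IncidenceMatrix(
        allotype=None,
        peptides=[candidates[i] for i in keep],
        patients=patients,
        present=np.array([cells[i] for i in keep], dtype=bool)
        if keep
        else np.zeros((0, len(patients)), dtype=bool),
    )
    sel = optimise_selection(matrix, iterations, seed)
    if hpv_calls is not None:
        by_status: dict[str, float] = {}
        for status in ("positive", "negative"):
            group = [
                pid for pid in patients
                if getattr(hpv_calls.get(pid), "status", None) == status
            ]
            if group:
                by_status[status] = 100.0 * sum(
                    1 for pid in group if pid in sel.covered_patients
                ) / len(group)
        sel.coverage_by_status = by_status
    return sel


def compose_patient(
    patient: PatientGenotype,
    warehouse: Sequence[WarehouseSelection],
    ligandome: Optional[Ligandome],
) -> PatientComposition:
    """Semi-personalised composition: union of the selections for the
    allotypes the patient carries, intersected with their ligandome."""
    selected: set[str] = set()
    for sel in warehouse:
        if sel.allotype is not None and sel.allotype in patient.class_i_alleles:
            selected |= set(sel.selected)
    presented = (
        selected & ligandome.class_i_peptides if ligandome is not None else set()
    )
    pct = 100.0 * len(presented) / len(selected) if selected else 0.0
    return PatientComposition(
        patient_id=patient.patient_id,
        selected_teps=selected,
        presented_teps=presented,
        pct_of_selected=pct,
    )


@dataclass
class CoverageReport:
    per_allotype: pd.DataFrame
    per_patient: pd.DataFrame
    summary: dict


def coverage_report(
    warehouse: Sequence[WarehouseSelection],
    cohort: Sequence[PatientGenotype],
    ligandomes: Mapping[str, Ligandome],
) -> CoverageReport:
    """Carrier coverage per allotype and composition sizes per patient."""
    allotype_rows = []
    for sel in warehouse:
        if sel.allotype is None:
            carriers = [g.patient_id for g in cohort]
        else:
            carriers = [g.patient_id for g in cohort if sel.allotype in g.class_i_alleles]
        covered = [pid for pid in carriers if pid in sel.covered_patients]
        allotype_rows.append(
            {
                "allotype": sel.allotype.render() if sel.allotype else "class_II",
                "n_selected": len(sel.selected),
                "n_carriers": len(carriers),
                "n_covered": len(covered),
                "coverage_pct": 100.0 * len(covered) / len(carriers) if carriers else 0.0,
                "n_runs": sel.n_runs,
                "n_qc_removed": len(sel.qc_removed),
            }
        )
    patient_rows = []
    for g in cohort:
        comp = compose_patient(g, warehouse, ligandomes.get(g.patient_id))
        patient_rows.append(
            {
                "patient_id": g.patient_id,
                "n_selected": len(comp.selected_teps),
                "n_presented": len(comp.presented_teps),
                "pct_of_selected": comp.pct_of_selected,
            }
        )
    per_patient = pd.DataFrame(
        patient_rows, columns=["patient_id", "n_selected", "n_presented", "pct_of_selected"]
    )
    summary = {}
    if len(per_patient):
        summary = {
            "median_n_selected": float(per_patient["n_selected"].median()),
            "median_n_presented": float(per_patient["n_presented"].median()),
            "median_pct_of_selected": float(per_patient["pct_of_selected"].median()),
            "range_n_selected": [int(per_patient["n_selected"].min()), int(per_patient["n_selected"].max())],
            "range_pct_of_selected": [
                float(per_patient["pct_of_selected"].min()),
                float(per_patient["pct_of_selected"].max()),
            ],
        }
    return CoverageReport(
        per_allotype=pd.DataFrame(
            allotype_rows,
            columns=[
                "allotype", "n_selected", "n_carriers", "n_covered",
                "coverage_pct", "n_runs", "n_qc_removed",
            ],
        ),
        per_patient=per_patient,
        summary=summary,
    )
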