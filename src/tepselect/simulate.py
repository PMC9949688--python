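"""Synthetic immunopeptidome cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: diploid HLA genotypes drawn from per-locus allele frequencies
under Hardy–Weinberg equilibrium, per-sample ligandome sizes coupled to
tissue mass through a bivariate lognormal, class-specific peptide length
distributions, an allotype-attached shared peptide pool plus
sample-private peptides, a controllable fraction of peptides planted
into the benign reference (the complement being the planted
tumour-exclusive set), spectral QC metrics with a controllable pass
fraction, and HPV oncogene read counts on either side of the calling
threshold.

Every table is driven by its own named random stream derived from one
global seed, so regenerating one table never perturbs the others, and
the full output is byte-identical for a fixed configuration.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional

import numpy as np

from .binding import MotifMatrix
from .hla import HLAAllele, parse_allele
from .records import (
    AMINO_ACIDS,
    BenignReference,
    HPV_ONCOGENES,
    OncogeneReadCounts,
    PatientGenotype,
    PeptideRecord,
)

__all__ = ["SimulationConfig", "SimulatedCohort", "PlantedTruth", "simulate_cohort", "simulate_genotypes"]

# German-population-like 2-field allele frequencies; each locus sums to 1
# so Hardy-Weinberg sampling needs no filler category.
DEFAULT_ALLELE_FREQS: dict[str, dict[str, float]] = {
    "A": {
        "HLA-A*02:01": 0.28, "HLA-A*01:01": 0.17, "HLA-A*03:01": 0.14,
        "HLA-A*24:02": 0.11, "HLA-A*11:01": 0.07, "HLA-A*68:01": 0.05,
        "HLA-A*26:01": 0.04, "HLA-A*25:01": 0.03, "HLA-A*32:01": 0.03,
        "HLA-A*31:01": 0.03, "HLA-A*29:02": 0.03, "HLA-A*23:01": 0.02,
    },
    "B": {
        "HLA-B*07:02": 0.14, "HLA-B*08:01": 0.11, "HLA-B*44:02": 0.10,
        "HLA-B*51:01": 0.06, "HLA-B*40:01": 0.06, "HLA-B*15:01": 0.06,
        "HLA-B*35:01": 0.06, "HLA-B*44:03": 0.05, "HLA-B*18:01": 0.05,
        "HLA-B*27:05": 0.04, "HLA-B*57:01": 0.03, "HLA-B*13:02": 0.03,
        "HLA-B*35:03": 0.03, "HLA-B*37:01": 0.02, "HLA-B*49:01": 0.02,
        "HLA-B*55:01": 0.02, "HLA-B*14:02": 0.02, "HLA-B*38:01": 0.02,
        "HLA-B*39:01": 0.02, "HLA-B*58:01": 0.02, "HLA-B*52:01": 0.02,
        "HLA-B*41:01": 0.01, "HLA-B*50:01": 0.01,
    },
    "C": {
        "HLA-C*07:01": 0.17, "HLA-C*04:01": 0.14, "HLA-C*07:02": 0.14,
        "HLA-C*06:02": 0.09, "HLA-C*03:04": 0.08, "HLA-C*05:01": 0.08,
        "HLA-C*12:03": 0.06, "HLA-C*03:03": 0.05, "HLA-C*02:02": 0.05,
        "HLA-C*01:02": 0.04, "HLA-C*08:02": 0.03, "HLA-C*15:02": 0.02,
        "HLA-C*16:01": 0.02, "HLA-C*14:02": 0.02, "HLA-C*12:02": 0.01,
    },
    "DRB1": {
        "HLA-DRB1*15:01": 0.15, "HLA-DRB1*07:01": 0.13, "HLA-DRB1*03:01": 0.12,
        "HLA-DRB1*01:01": 0.10, "HLA-DRB1*11:01": 0.09, "HLA-DRB1*04:01": 0.08,
        "HLA-DRB1*13:01": 0.07, "HLA-DRB1*08:01": 0.05, "HLA-DRB1*13:02": 0.05,
        "HLA-DRB1*14:01": 0.04, "HLA-DRB1*12:01": 0.04, "HLA-DRB1*16:01": 0.04,
        "HLA-DRB1*10:01": 0.04,
    },
    "DQB1": {
        "HLA-DQB1*03:01": 0.20, "HLA-DQB1*06:02": 0.14, "HLA-DQB1*02:01": 0.14,
        "HLA-DQB1*05:01": 0.13, "HLA-DQB1*03:02": 0.10, "HLA-DQB1*06:03": 0.08,
        "HLA-DQB1*04:02": 0.06, "HLA-DQB1*05:03": 0.05, "HLA-DQB1*03:03": 0.05,
        "HLA-DQB1*06:04": 0.05,
    },
    "DPB1": {
        "HLA-DPB1*04:01": 0.42, "HLA-DPB1*02:01": 0.14, "HLA-DPB1*04:02": 0.12,
        "HLA-DPB1*03:01": 0.10, "HLA-DPB1*01:01": 0.07, "HLA-DPB1*06:01": 0.05,
        "HLA-DPB1*05:01": 0.04, "HLA-DPB1*11:01": 0.03, "HLA-DPB1*13:01": 0.02,
        "HLA-DPB1*10:01": 0.01,
    },
}

# Class I: 9-mers dominate at 70%.
DEFAULT_LENGTH_DIST_I: dict[int, float] = {8: 0.10, 9: 0.70, 10: 0.13, 11: 0.07}

# Class II: broad 8-25 with the mode at 15 residues (17%).
DEFAULT_LENGTH_DIST_II: dict[int, float] = {
    8: 0.010, 9: 0.020, 10: 0.030, 11: 0.050, 12: 0.080, 13: 0.110,
    14: 0.140, 15: 0.170, 16: 0.130, 17: 0.090, 18: 0.060, 19: 0.040,
    20: 0.030, 21: 0.020, 22: 0.010, 23: 0.005, 24: 0.003, 25: 0.002,
}

DEFAULT_HPV_TYPE_PROBS = {
    "HPV-16": 19 / 22, "HPV-35": 1 / 22, "HPV-58": 1 / 22, "HPV-59": 1 / 22,
}

BENIGN_TISSUES = (
    "tonsil", "blood", "lung", "liver", "kidney",
    "colon", "skin", "spleen", "thymus", "brain",
)


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the cohort scale and marginal statistics the
    analysis was designed around: 40 patients, 55% HPV-positive, a mean
    of 1338 class I and 702 class II peptides per sample, 70% class I
    9-mers, a class II length mode of 15 residues (17%), a mass-yield
    Pearson correlation of ~0.46, and a 90% spectral-QC pass fraction.
    """

    n_patients: int = 40
    allele_freqs: Mapping[str, Mapping[str, float]] = dc_field(
        default_factory=lambda: DEFAULT_ALLELE_FREQS
    )
    mean_ligandome_size_i: float = 1338.0
    mean_ligandome_size_ii: float = 702.0
    length_dist_i: Mapping[int, float] = dc_field(default_factory=lambda: DEFAULT_LENGTH_DIST_I)
    length_dist_ii: Mapping[int, float] = dc_field(default_factory=lambda: DEFAULT_LENGTH_DIST_II)
    benign_overlap_frac: float = 0.77
    shared_peptide_pool_size: int = 2000
    hpv_positive_frac: float = 0.55
    mass_yield_r: float = 0.4645
    qc_pass_frac: float = 0.90
    seed: int = 0
    # secondary knobs
    binder_frac: float = 0.94           # class I presented peptides that are binders
    shared_detect_prob: float = 0.5     # P(carrier sample presents a shared-pool peptide)
    benign_background_factor: float = 2.0  # benign-only peptides per tumour-unique peptide
    decoy_frac: float = 0.02            # extra records failing the q-value filter
    hpv_type_probs: Mapping[str, float] = dc_field(default_factory=lambda: DEFAULT_HPV_TYPE_PROBS)
    mean_tissue_mass_mg: float = 150.0
    lognormal_sigma: float = 0.45
    peptides_per_protein: float = 2.4

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be ≥ 1")
        for locus, freqs in self.allele_freqs.items():
            s = sum(freqs.values())
            if s > 1.0 + 1e-9 or any(f < 0 for f in freqs.values()):
                raise ConfigError(f"invalid allele frequencies at locus {locus} (sum {s:.4f})")
        for name, dist in (("length_dist_i", self.length_dist_i), ("length_dist_ii", self.length_dist_ii)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1")
        for name in ("benign_overlap_frac", "hpv_positive_frac", "qc_pass_frac", "binder_frac",
                     "shared_detect_prob", "decoy_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.mass_yield_r <= 1.0:
            raise ConfigError("mass_yield_r must be in [-1, 1]")


@dataclass
class PlantedTruth:
    """Generator bookkeeping used as the oracle in recovery tests."""

    sample_peptides: dict[str, dict[str, set[str]]]  # class → sample → peptides
    benign_planted: dict[str, set[str]]
    tep: dict[str, set[str]]                         # class → tumour-exclusive peptides
    shared_pool: dict[str, str]                      # class I pool peptide → allotype
    binder_assignments: dict[str, dict[str, str]]    # sample → peptide → allotype
    qc_pass: set[str]
    qc_fail: set[str]
    hpv_status: dict[str, str]


@dataclass
class SimulatedCohort:
    genotypes: list[PatientGenotype]
    records: list[PeptideRecord]
    benign: BenignReference
    oncogene_counts: list[OncogeneReadCounts]
    motifs: list[MotifMatrix]
    source_proteins: dict[str, set[str]]
    planted: PlantedTruth
    config: SimulationConfig


def _stream(seed: int, name: str) -> np.random.Generator:
    """One named, reproducible random stream per generated table."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def simulate_genotypes(
    n_patients: int,
    allele_freqs: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
) -> list[tuple[HLAAllele, ...]]:
    """Draw two alleles per locus per patient (Hardy–Weinberg, loci independent)."""
    per_locus: list[np.ndarray] = []
    allele_objects: list[list[HLAAllele]] = []
    for locus in allele_freqs:
        names = list(allele_freqs[locus])
        probs = np.array([allele_freqs[locus][a] for a in names], dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(names), size=(n_patients, 2), p=probs)
        per_locus.append(draws)
        allele_objects.append([parse_allele(a) for a in names])
    out = []
    for i in range(n_patients):
        alleles = []
        for loc_idx in range(len(per_locus)):
            for a in per_locus[loc_idx][i]:
                alleles.append(allele_objects[loc_idx][a])
        out.append(tuple(alleles))
    return out


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray, seen: set[str]) -> list[str]:
    """Fresh uniform-random peptides of the requested lengths, unique
    among themselves and against `seen` (which is updated)."""
    out: list[str] = []
    for length in lengths:
        while True:
            idx = rng.integers(0, len(AMINO_ACIDS), int(length))
            seq = "".join(AMINO_ACIDS[i] for i in idx)
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                break
    return out


def _make_motifs(alleles: list[HLAAllele], rng: np.random.Generator) -> dict[tuple[str, int], MotifMatrix]:
    """Random additive motifs for lengths 8-11 per class I allele.

    The threshold is the minimum score reachable by choosing any top-5
    residue at each position, so motif-sampled peptides always pass.
    """
    motifs: dict[tuple[str, int], MotifMatrix] = {}
    for allele in alleles:
        for length in (8, 9, 10, 11):
            w = rng.uniform(0.0, 1.0, size=(length, len(AMINO_ACIDS)))
            top5_min = np.sort(w, axis=1)[:, -5].sum()
            motifs[(allele.render(), length)] = MotifMatrix(
                allele=allele, length=length, weights=w, threshold=float(top5_min)
            )
    return motifs


def _motif_peptides(
    motif: MotifMatrix, n: int, rng: np.random.Generator, seen: set[str]
) -> list[str]:
    """Sample `n` fresh peptides from a motif's top-5 residues per position."""
    top5 = np.argsort(motif.weights, axis=1)[:, -5:]  # (L, 5)
    out: list[str] = []
    while len(out) < n:
        picks = rng.integers(0, 5, size=motif.length)
        seq = "".join(AMINO_ACIDS[top5[i, picks[i]]] for i in range(motif.length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _draw_lengths(rng: np.random.Generator, dist: Mapping[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[int(l)] for l in lengths], dtype=float)
    return rng.choice(lengths, size=n, p=probs / probs.sum())


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one synthetic cohort; deterministic for a given config."""
    cfg = config
    seed = cfg.seed

    # ---- genotypes ---------------------------------------------------
    rng_geno = _stream(seed, "genotypes")
    allele_sets = simulate_genotypes(cfg.n_patients, cfg.allele_freqs, rng_geno)
    patient_ids = [f"OPSCC{i + 1:03d}" for i in range(cfg.n_patients)]

    # ---- HPV status and oncogene read counts -------------------------
    rng_hpv = _stream(seed, "hpv")
    n_pos = int(round(cfg.n_patients * cfg.hpv_positive_frac))
    pos_idx = set(rng_hpv.permutation(cfg.n_patients)[:n_pos].tolist())
    type_names = list(cfg.hpv_type_probs)
    type_probs = np.array([cfg.hpv_type_probs[t] for t in type_names], dtype=float)
    type_probs = type_probs / type_probs.sum()

    hpv_status: dict[str, str] = {}
    hpv_types: dict[str, Optional[str]] = {}
    oncogene_counts: list[OncogeneReadCounts] = []
    for i, pid in enumerate(patient_ids):
        if i in pos_idx:
            hpv_type = type_names[rng_hpv.choice(len(type_names), p=type_probs)]
            counts = {
                g: int(rng_hpv.lognormal(4.0, 1.0)) for g in HPV_ONCOGENES
            }
            counts["E6"] = 500 + int(rng_hpv.lognormal(6.5, 0.8))
            counts["E7"] = 500 + int(rng_hpv.lognormal(6.5, 0.8))
            oncogene_counts.append(OncogeneReadCounts(patient_id=pid, counts={hpv_type: counts}))
            hpv_status[pid] = "positive"
            hpv_types[pid] = hpv_type
        else:
            total = int(min(rng_hpv.poisson(8), 400))
            split = rng_hpv.multinomial(total, np.full(8, 1 / 8))
            counts = {g: int(k) for g, k in zip(HPV_ONCOGENES, split)}
            oncogene_counts.append(
                OncogeneReadCounts(patient_id=pid, counts={"HPV-16": counts})
            )
            hpv_status[pid] = "negative"
            hpv_types[pid] = None

    # ---- tissue mass coupled to class I yield ------------------------
    rng_mass = _stream(seed, "mass_yield")
    r = cfg.mass_yield_r
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng_mass.multivariate_normal(np.zeros(2), cov, size=cfg.n_patients)
    sigma = cfg.lognormal_sigma
    masses = np.exp(math.log(cfg.mean_tissue_mass_mg) + sigma * z[:, 0])
    mu_yield = math.log(cfg.mean_ligandome_size_i) - sigma**2 / 2
    sizes_i = np.maximum(30, np.round(np.exp(mu_yield + sigma * z[:, 1]))).astype(int)
    mu_yield_ii = math.log(cfg.mean_ligandome_size_ii) - sigma**2 / 2
    sizes_ii = np.maximum(
        20, np.round(rng_mass.lognormal(mu_yield_ii, sigma, size=cfg.n_patients))
    ).astype(int)

    # ---- motifs and shared peptide pools -----------------------------
    rng_pool = _stream(seed, "peptide_pools")
    class_i_alleles = sorted(
        {a for alleles in allele_sets for a in alleles if a.hla_class == "I"}
    ) + [parse_allele(a) for loc in ("A", "B", "C") for a in cfg.allele_freqs.get(loc, {})]
    class_i_alleles = sorted(set(class_i_alleles))
    motif_index = _make_motifs(class_i_alleles, rng_pool)

    seen: set[str] = set()
    # class I shared pool: each peptide attached to one allotype, drawn
    # proportionally to that allotype's population frequency
    freq_items = [
        (parse_allele(name), f)
        for loc in ("A", "B", "C")
        for name, f in cfg.allele_freqs.get(loc, {}).items()
    ]
    pool_probs = np.array([f for _, f in freq_items], dtype=float)
    pool_probs = pool_probs / pool_probs.sum()
    pool_lengths = _draw_lengths(rng_pool, cfg.length_dist_i, cfg.shared_peptide_pool_size)
    pool_allotypes = rng_pool.choice(len(freq_items), size=cfg.shared_peptide_pool_size, p=pool_probs)
    shared_pool: dict[str, HLAAllele] = {}
    for k in range(cfg.shared_peptide_pool_size):
        allele = freq_items[pool_allotypes[k]][0]
        motif = motif_index[(allele.render(), int(pool_lengths[k]))]
        seq = _motif_peptides(motif, 1, rng_pool, seen)[0]
        shared_pool[seq] = allele

    # class II shared pool (allotype-agnostic)
    n_pool_ii = cfg.shared_peptide_pool_size // 2
    pool_ii = _random_sequences(rng_pool, _draw_lengths(rng_pool, cfg.length_dist_ii, n_pool_ii), seen)

    # ---- per-sample ligandomes ---------------------------------------
    rng_samp = _stream(seed, "samples")
    pool_i_items = list(shared_pool.items())
    sample_peptides: dict[str, dict[str, set[str]]] = {"I": {}, "II": {}}
    binder_assignments: dict[str, dict[str, str]] = {}
    records: list[PeptideRecord] = []
    record_specs: list[tuple[str, str, str, Optional[HLAAllele]]] = []  # seq, sample, class, allele

    for i, pid in enumerate(patient_ids):
        patient_class_i = tuple(a for a in allele_sets[i] if a.hla_class == "I")
        size_i = int(sizes_i[i])
        n_binders = int(round(cfg.binder_frac * size_i))

        carried = {a.render() for a in patient_class_i}
        candidates = [
            (seq, al) for seq, al in pool_i_items if al.render() in carried
        ]
        detect = rng_samp.random(len(candidates)) < cfg.shared_detect_prob
        shared_here = [c for c, d in zip(candidates, detect) if d][:n_binders]

        n_private = max(0, n_binders - len(shared_here))
        private_here: list[tuple[str, HLAAllele]] = []
        if n_private and patient_class_i:
            lengths = _draw_lengths(rng_samp, cfg.length_dist_i, n_private)
            allele_picks = rng_samp.integers(0, len(patient_class_i), n_private)
            for length, a_idx in zip(lengths, allele_picks):
                allele = patient_class_i[a_idx]
                motif = motif_index[(allele.render(), int(length))]
                seq = _motif_peptides(motif, 1, rng_samp, seen)[0]
                private_here.append((seq, allele))

        n_nonbinders = size_i - n_binders
        nonbinders = _random_sequences(
            rng_samp, _draw_lengths(rng_samp, cfg.length_dist_i, n_nonbinders), seen
        )

        class_i_here = {s for s, _ in shared_here} | {s for s, _ in private_here} | set(nonbinders)
        sample_peptides["I"][pid] = class_i_here
        binder_assignments[pid] = {s: al.render() for s, al in shared_here + private_here}
        for s, al in shared_here + private_here:
            record_specs.append((s, pid, "I", al))
        for s in nonbinders:
            record_specs.append((s, pid, "I", None))

        # class II: shared pool draws plus private peptides
        size_ii = int(sizes_ii[i])
        n_shared_ii = min(len(pool_ii), int(round(0.4 * size_ii)))
        shared_ii_idx = rng_samp.choice(len(pool_ii), size=n_shared_ii, replace=False)
        shared_ii = [pool_ii[j] for j in shared_ii_idx]
        private_ii = _random_sequences(
            rng_samp, _draw_lengths(rng_samp, cfg.length_dist_ii, size_ii - n_shared_ii), seen
        )
        sample_peptides["II"][pid] = set(shared_ii) | set(private_ii)
        for s in shared_ii + private_ii:
            record_specs.append((s, pid, "II", None))

    # ---- benign reference: overlap + background ----------------------
    rng_benign = _stream(seed, "benign")
    unique_by_class = {
        cls: sorted(set().union(*sample_peptides[cls].values()))
        for cls in ("I", "II")
    }
    benign_planted: dict[str, set[str]] = {}
    tep: dict[str, set[str]] = {}
    benign_sets: dict[str, set[str]] = {"I": set(), "II": set()}
    for cls in ("I", "II"):
        uniq = unique_by_class[cls]
        mask = rng_benign.random(len(uniq)) < cfg.benign_overlap_frac
        planted = {s for s, m in zip(uniq, mask) if m}
        benign_planted[cls] = planted
        tep[cls] = set(uniq) - planted
        n_extra = int(round(cfg.benign_background_factor * len(uniq)))
        dist = cfg.length_dist_i if cls == "I" else cfg.length_dist_ii
        extra = _random_sequences(rng_benign, _draw_lengths(rng_benign, dist, n_extra), seen)
        benign_sets[cls] = planted | set(extra)
    tissue_index: dict[str, set[str]] = {}
    for cls in ("I", "II"):
        for s in sorted(benign_sets[cls]):  # sorted: RNG order must not depend on set hashing
            k = 1 + int(rng_benign.random() < 0.3)
            picks = rng_benign.choice(len(BENIGN_TISSUES), size=k, replace=False)
            tissue_index.setdefault(s, set()).update(BENIGN_TISSUES[j] for j in picks)
    benign = BenignReference(
        peptides_by_class=benign_sets,
        tissue_index=tissue_index,
        n_samples={"I": 424, "II": 369},
    )

    # ---- spectral QC metrics and q-values ----------------------------
    rng_qc = _stream(seed, "qc_metrics")
    all_unique = sorted(set(unique_by_class["I"]) | set(unique_by_class["II"]))
    qc_pass_mask = rng_qc.random(len(all_unique)) < cfg.qc_pass_frac
    metrics: dict[str, tuple[int, float, float]] = {}
    qc_pass_set: set[str] = set()
    for s, ok in zip(all_unique, qc_pass_mask):
        if ok:
            m = (2 + int(rng_qc.poisson(1.5)),
                 1.5 + float(rng_qc.exponential(0.7)),
                 0.2 + float(rng_qc.uniform(0.0, 0.3)))
            qc_pass_set.add(s)
        else:
            mode = int(rng_qc.integers(0, 3))
            psm = 1 if mode == 0 else 2 + int(rng_qc.poisson(1.5))
            xc = float(rng_qc.uniform(0.5, 1.49)) if mode == 1 else 1.5 + float(rng_qc.exponential(0.7))
            dcn = float(rng_qc.uniform(0.0, 0.19)) if mode == 2 else 0.2 + float(rng_qc.uniform(0.0, 0.3))
            m = (psm, xc, dcn)
        metrics[s] = m

    for seq, pid, cls, allele in record_specs:
        psm, xc, dcn = metrics[seq]
        records.append(
            PeptideRecord(
                sequence=seq, sample_id=pid, hla_class=cls, assigned_allele=allele,
                psm_count=psm, xcorr=xc, delta_cn=dcn,
                q_value=float(rng_qc.uniform(0.0, 0.05)),
            )
        )
    # decoy identifications above the q-value gate, removed by filtering
    for i, pid in enumerate(patient_ids):
        n_decoys = int(round(cfg.decoy_frac * sizes_i[i]))
        for seq in _random_sequences(
            rng_qc, _draw_lengths(rng_qc, cfg.length_dist_i, n_decoys), seen
        ):
            records.append(
                PeptideRecord(
                    sequence=seq, sample_id=pid, hla_class="I",
                    psm_count=1, xcorr=1.0, delta_cn=0.1,
                    q_value=float(rng_qc.uniform(0.051, 0.5)),
                )
            )

    # ---- source proteins ---------------------------------------------
    rng_prot = _stream(seed, "source_proteins")
    source_proteins: dict[str, set[str]] = {}
    for cls in ("I", "II"):
        uniq = unique_by_class[cls]
        n_prot = max(1, int(round(len(uniq) / cfg.peptides_per_protein)))
        ranks = np.arange(1, n_prot + 1, dtype=float)
        probs = ranks**-0.7
        probs /= probs.sum()
        assignment = rng_prot.choice(n_prot, size=len(uniq), p=probs)
        for s, j in zip(uniq, assignment):
            source_proteins.setdefault(s, set()).add(f"PROT_{cls}_{j + 1:05d}")

    # ---- assemble -----------------------------------------------------
    genotypes = [
        PatientGenotype(
            patient_id=pid,
            alleles=allele_sets[i],
            hpv_status=hpv_status[pid],
            hpv_type=hpv_types[pid],
            metadata={"sex": "male" if _stream(seed, f"meta{i}").random() < 0.825 else "female"},
            tissue_mass_mg=float(masses[i]),
        )
        for i, pid in enumerate(patient_ids)
    ]
    planted = PlantedTruth(
        sample_peptides=sample_peptides,
        benign_planted=benign_planted,
        tep=tep,
        shared_pool={s: a.render() for s, a in shared_pool.items()},
        binder_assignments=binder_assignments,
        qc_pass=qc_pass_set,
        qc_fail=set(all_unique) - qc_pass_set,
        hpv_status=dict(hpv_status),
    )
    return SimulatedCohort(
        genotypes=genotypes,
        records=records,
        benign=benign,
        oncogene_counts=oncogene_counts,
        motifs=list(motif_index.values()),
        source_proteins=source_proteins,
        planted=planted,
        config=cfg,
    )
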