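"""Synthetic germplasm collections with a machine-readable truth log.

The generator emulates the statistical structure the analysis modules
assume: several species diverged from a common ancestral gene pool under
the Balding-Nichols model (per-species allele frequencies Beta-distributed
around the ancestral frequency, with divergence parameter phi equal to the
expected Fst), Hardy-Weinberg genotypes within species, Mendelian pedigrees,
clonal bud-sport lineages with a per-locus somatic mutation rate, missing
calls, and name metadata with planted synonym / homonym / replicate errors.

Default configuration mirrors the study conditions of a Malus germplasm
collection typed at ~100 biallelic fragment-length markers: seven species
at the structure-subset sample sizes, divergence spread over Fst 0.02-0.13,
and three large clonal sport lineages.

All randomness flows from a single seeded numpy Generator; nothing reads
global random state, so equal seeds give byte-identical collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import AccessionRecord, Call, GenotypeTable


@dataclass
class PedigreeSpec:
    parent1: str  # accession id of an already-generated founder
    parent2: str
    n_offspring: int = 1


@dataclass
class CloneSpec:
    founder: str  # accession id of the wildtype cultivar
    n_clones: int
    mu: float = 0.005  # somatic mutation probability per locus per clone


@dataclass
class NameErrorSpec:
    n_synonym_pairs: int = 10  # same genotype planted under two names
    n_homonym_pairs: int = 10  # one name reused for two genotypes
    n_replicate_pairs: int = 4  # same genotype, same name


@dataclass
class SimulationConfig:
    seed: int = 0
    n_markers: int = 102
    species_names: tuple[str, ...] = (
        "species_A",
        "species_B",
        "species_C",
        "species_D",
        "species_E",
        "species_F",
        "species_G",
    )
    #: per-species Balding-Nichols divergence, spanning the observed
    #: between-species Fst range 0.02-0.13
    phi: tuple[float, ...] = (0.02, 0.04, 0.05, 0.07, 0.09, 0.11, 0.13)
    #: structure-subset sample sizes per species
    n_per_species: tuple[int, ...] = (27, 42, 20, 30, 19, 22, 13)
    ancestral_beta: tuple[float, float] = (1.0, 1.0)
    ancestral_bounds: tuple[float, float] = (0.05, 0.95)
    pedigree_spec: list[PedigreeSpec] = field(default_factory=list)
    clone_spec: list[CloneSpec] = field(default_factory=list)
    missing_rate: float = 0.01
    name_errors: NameErrorSpec = field(default_factory=NameErrorSpec)

    def __post_init__(self) -> None:
        if len(self.phi) != len(self.species_names) or len(self.n_per_species) != len(
            self.species_names
        ):
            raise ValueError("phi / n_per_species must match species_names")
        if not all(0 < f < 1 for f in self.phi):
            raise ValueError("phi must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for cs in self.clone_spec:
            if not 0 <= cs.mu <= 1:
                raise ValueError("clone mutation rate must lie in [0, 1]")


def default_config(seed: int = 0) -> SimulationConfig:
    """The study-scale default: seven species, pedigreed offspring, and
    three bud-sport lineages (160/60/60 clones) from species_A founders."""
    cfg = SimulationConfig(seed=seed)
    cfg.pedigree_spec = [
        PedigreeSpec(f"species_A_{2 * i:03d}", f"species_A_{2 * i + 1:03d}", 2)
        for i in range(8)
    ]
    cfg.clone_spec = [
        CloneSpec("species_A_000", 160, 0.005),
        CloneSpec("species_A_002", 60, 0.005),
        CloneSpec("species_A_004", 60, 0.005),
    ]
    return cfg


# -- primitive generators --------------------------------------------------


def simulate_ancestral_freqs(
    n_markers: int,
    rng: np.random.Generator,
    beta: tuple[float, float] = (1.0, 1.0),
    bounds: tuple[float, float] = (0.05, 0.95),
) -> np.ndarray:
    """Ancestral frequencies ~ Beta(a, b) truncated to ``bounds`` (rejection)."""
    lo, hi = bounds
    out = np.empty(n_markers)
    filled = 0
    while filled < n_markers:
        draw = rng.beta(beta[0], beta[1], size=2 * (n_markers - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n_markers - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def simulate_species_freqs(
    ancestral: np.ndarray, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols draw: Beta(p(1-phi)/phi, (1-p)(1-phi)/phi) per marker,
    so E[freq] = p and Var = phi * p(1-p)."""
    if not 0 < phi < 1:
        raise ValueError("phi must lie in (0, 1)")
    lam = (1.0 - phi) / phi
    return rng.beta(ancestral * lam, (1.0 - ancestral) * lam)


def simulate_genotypes(
    freqs: np.ndarray, n: int, rng: np.random.Generator, allele_sizes=None
) -> list[list[Call]]:
    """Hardy-Weinberg genotypes: two alleles drawn independently per
    individual per locus. ``freqs`` is the insertion-allele frequency per
    marker; ``allele_sizes`` is a per-marker (size_D, size_I) list (defaults
    to codes 1/2).
    """
    L = len(freqs)
    if allele_sizes is None:
        allele_sizes = [(1, 2)] * L
    dose = rng.binomial(1, freqs, size=(n, 2, L))  # gamete carries I?
    rows: list[list[Call]] = []
    for i in range(n):
        row: list[Call] = []
        for j in range(L):
            sd, si = allele_sizes[j]
            a = si if dose[i, 0, j] else sd
            b = si if dose[i, 1, j] else sd
            row.append(tuple(sorted((a, b))))
        rows.append(row)
    return rows


def simulate_genotype_counts(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Hardy-Weinberg sampling for biallelic loci.

    Returns per-locus genotype counts (n_II, n_ID, n_DD) for a sample of
    ``n`` diploids; ``freqs`` is the insertion-allele frequency per locus.
    Used by simulation-heavy calibration checks where building full call
    tables would dominate the runtime.
    """
    dose = rng.binomial(2, freqs, size=(n, len(freqs)))
    n_ii = (dose == 2).sum(axis=0)
    n_id = (dose == 1).sum(axis=0)
    n_dd = (dose == 0).sum(axis=0)
    return n_ii, n_id, n_dd


def simulate_offspring(
    p1_calls: list[Call], p2_calls: list[Call], n: int, rng: np.random.Generator
) -> list[list[Call]]:
    """Mendelian transmission: one allele sampled uniformly from each parent
    per locus; loci where either parent is missing come out missing."""
    rows: list[list[Call]] = []
    for _ in range(n):
        row: list[Call] = []
        for c1, c2 in zip(p1_calls, p2_calls):
            if c1 is None or c2 is None:
                row.append(None)
                continue
            a = c1[rng.integers(len(c1))]
            b = c2[rng.integers(len(c2))]
            row.append(tuple(sorted((a, b))))
        rows.append(row)
    return rows


def simulate_clones(
    founder_calls: list[Call],
    n: int,
    mu: float,
    rng: np.random.Generator,
    allele_sets: list[tuple[int, ...]],
) -> tuple[list[list[Call]], list[tuple[int, int]]]:
    """Clonal copies with somatic mutations.

    Each locus of each clone mutates independently with probability ``mu``:
    one allele of the call is replaced by a different allele from the
    marker's allele set (no new fragment lengths — capillary genotyping
    rarely reveals novel sizes). Returns the calls and a log of mutated
    (clone_index, locus_index) cells.
    """
    rows: list[list[Call]] = []
    log: list[tuple[int, int]] = []
    for i in range(n):
        row: list[Call] = []
        for j, c in enumerate(founder_calls):
            if c is None:
                row.append(None)
                continue
            if rng.random() < mu:
                which = int(rng.integers(2))
                current = c[which]
                alts = [a for a in allele_sets[j] if a != current]
                if alts:
                    new = alts[int(rng.integers(len(alts)))]
                    mutated = list(c)
                    mutated[which] = new
                    row.append(tuple(sorted(mutated)))
                    log.append((i, j))
                    continue
            row.append(c)
        rows.append(row)
    return rows, log


# -- full collections ------------------------------------------------------


@dataclass
class TruthRecord:
    """Everything the generator decided, for downstream verification."""

    ancestral_freqs: list[float]
    species_freqs: dict[str, list[float]]  # insertion-allele frequency per marker
    allele_sizes: list[tuple[int, int]]  # (size_D, size_I) per marker
    species_of: dict[str, str]
    parents_of: dict[str, tuple[str, str]]
    clone_family_of: dict[str, str]  # clone accession -> founder accession
    name_class_of: dict[str, str]  # planted label: synonym|homonym|replicate
    mutated_cells: list[tuple[str, str]]  # (accession_id, marker_id)
    missing_cells: list[tuple[str, str]]

    def to_json_dict(self) -> dict:
        return {
            "ancestral_freqs": self.ancestral_freqs,
            "species_freqs": self.species_freqs,
            "allele_sizes": [list(t) for t in self.allele_sizes],
            "species_of": self.species_of,
            "parents_of": {k: list(v) for k, v in self.parents_of.items()},
            "clone_family_of": self.clone_family_of,
            "name_class_of": self.name_class_of,
            "mutated_cells": [list(t) for t in self.mutated_cells],
            "missing_cells": [list(t) for t in self.missing_cells],
        }


def assemble_collection(config: SimulationConfig) -> tuple[GenotypeTable, TruthRecord]:
    """Merge species samples, pedigrees and clone lineages; apply missing
    data and plant name-metadata errors. Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    L = config.n_markers
    markers = [f"C{(j % 17) + 1:02d}{j + 1:03d}" for j in range(L)]
    ancestral = simulate_ancestral_freqs(L, rng, config.ancestral_beta, config.ancestral_bounds)
    sizes_d = rng.integers(80, 300, size=L)
    diffs = rng.integers(50, 401, size=L)
    allele_sizes = [(int(d), int(d + g)) for d, g in zip(sizes_d, diffs)]
    allele_sets = [tuple(sorted(t)) for t in allele_sizes]

    accessions: list[AccessionRecord] = []
    calls: list[list[Call]] = []
    truth = TruthRecord([float(p) for p in ancestral], {}, allele_sizes, {}, {}, {}, {}, [], [])

    def add(acc: AccessionRecord, row: list[Call]) -> None:
        accessions.append(acc)
        calls.append(row)

    for sp, phi, n in zip(config.species_names, config.phi, config.n_per_species):
        freqs = simulate_species_freqs(ancestral, phi, rng)
        truth.species_freqs[sp] = [float(f) for f in freqs]
        rows = simulate_genotypes(freqs, n, rng, allele_sizes)
        for i, row in enumerate(rows):
            acc_id = f"{sp}_{i:03d}"
            add(AccessionRecord(acc_id, name=acc_id, species=sp), row)
            truth.species_of[acc_id] = sp
    index = {a.accession_id: i for i, a in enumerate(accessions)}

    for ped in config.pedigree_spec:
        for pid in (ped.parent1, ped.parent2):
            if pid not in index:
                raise ValueError(f"pedigree parent {pid!r} not generated")
        rows = simulate_offspring(
            calls[index[ped.parent1]], calls[index[ped.parent2]], ped.n_offspring, rng
        )
        for k, row in enumerate(rows):
            acc_id = f"off_{ped.parent1}x{ped.parent2}_{k:02d}"
            sp = accessions[index[ped.parent1]].species
            add(
                AccessionRecord(
                    acc_id,
                    name=acc_id,
                    species=sp,
                    parent1=ped.parent1,
                    parent2=ped.parent2,
                ),
                row,
            )
            truth.species_of[acc_id] = sp
            truth.parents_of[acc_id] = (ped.parent1, ped.parent2)
            index[acc_id] = len(accessions) - 1

    for cs in config.clone_spec:
        if cs.founder not in index:
            raise ValueError(f"clone founder {cs.founder!r} not generated")
        fi = index[cs.founder]
        accessions[fi].lineage_group = cs.founder
        rows, log = simulate_clones(calls[fi], cs.n_clones, cs.mu, rng, allele_sets)
        for k, row in enumerate(rows):
            acc_id = f"sport_{cs.founder}_{k:03d}"
            sp = accessions[fi].species
            add(
                AccessionRecord(
                    acc_id, name=acc_id, species=sp, lineage_group=cs.founder
                ),
                row,
            )
            truth.species_of[acc_id] = sp
            truth.clone_family_of[acc_id] = cs.founder
            index[acc_id] = len(accessions) - 1
        for ci, mj in log:
            truth.mutated_cells.append((f"sport_{cs.founder}_{ci:03d}", markers[mj]))

    # -- planted name errors ----------------------------------------------
    ne = config.name_errors
    n_total = len(accessions)
    # disjoint source draws keep each planted relation unambiguous in the log
    n_draw = ne.n_synonym_pairs + ne.n_replicate_pairs + ne.n_homonym_pairs
    if n_draw > n_total:
        raise ValueError("more planted name errors than accessions")
    drawn = rng.choice(n_total, size=n_draw, replace=False)
    base_ids = drawn[: ne.n_synonym_pairs]
    rep_ids = drawn[ne.n_synonym_pairs : ne.n_synonym_pairs + ne.n_replicate_pairs]
    hom_ids = drawn[ne.n_synonym_pairs + ne.n_replicate_pairs :]
    # synonyms: duplicate an accession's genotype under a fresh name
    for k, bi in enumerate(base_ids):
        src = accessions[int(bi)]
        acc_id = f"syn_{k:02d}"
        add(
            AccessionRecord(acc_id, name=f"alias of nobody {k}", species=src.species),
            list(calls[int(bi)]),
        )
        truth.species_of[acc_id] = src.species
        truth.name_class_of[acc_id] = "synonym"
        truth.name_class_of.setdefault(src.accession_id, "synonym")
    # replicates: same genotype AND same name
    for k, bi in enumerate(rep_ids):
        src = accessions[int(bi)]
        acc_id = f"rep_{k:02d}"
        add(AccessionRecord(acc_id, name=src.name, species=src.species), list(calls[int(bi)]))
        truth.species_of[acc_id] = src.species
        truth.name_class_of[acc_id] = "replicate"
        truth.name_class_of.setdefault(src.accession_id, "replicate")
    # homonyms: reuse a name for an unrelated genotype
    for k, bi in enumerate(hom_ids):
        src = accessions[int(bi)]
        sp = config.species_names[0]
        freqs = np.asarray(truth.species_freqs[sp])
        row = simulate_genotypes(freqs, 1, rng, allele_sizes)[0]
        acc_id = f"hom_{k:02d}"
        add(AccessionRecord(acc_id, name=src.name, species=sp), row)
        truth.species_of[acc_id] = sp
        truth.name_class_of[acc_id] = "homonym"
        truth.name_class_of.setdefault(src.accession_id, "homonym")

    # -- missingness -------------------------------------------------------
    if config.missing_rate > 0:
        mask = rng.random((len(accessions), L)) < config.missing_rate
        for i in range(len(accessions)):
            for j in range(L):
                if mask[i, j] and calls[i][j] is not None:
                    calls[i][j] = None
                    truth.missing_cells.append((accessions[i].accession_id, markers[j]))

    return GenotypeTable(markers, accessions, calls), truth
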