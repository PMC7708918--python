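"""Mendelian-exclusion parentage analysis for co-dominant markers.

A duo (offspring, one parent) is compatible at a locus when the two allele
multisets share at least one allele; a trio is compatible when the
offspring's two alleles can be drawn one from each proposed parent. A
hypothesis is accepted when the fraction of compatible informative loci
(the confidence C) exceeds ``min_confidence`` AND the number of mismatching
loci is at most ``threshold`` — the mismatch allowance absorbs somatic
mutations and null alleles. Defaults C > 0.98, threshold = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genotypes import Call, GenotypeTable
from .identity import group_by_signature

UNKNOWN = "UNKNOWN"

COMPATIBLE, INCOMPATIBLE, UNINFORMATIVE = "compatible", "incompatible", "uninformative"


def duo_compatible(offspring: Call, parent: Call) -> str:
    if offspring is None or parent is None:
        return UNINFORMATIVE
    return COMPATIBLE if set(offspring) & set(parent) else INCOMPATIBLE


def trio_compatible(offspring: Call, p1: Call, p2: Call) -> str:
    if offspring is None or p1 is None or p2 is None:
        return UNINFORMATIVE
    o = sorted(offspring)
    if len(o) == 1:
        o = [o[0], o[0]]
    a, b = o[0], o[-1]
    s1, s2 = set(p1), set(p2)
    ok = (a in s1 and b in s2) or (b in s1 and a in s2)
    return COMPATIBLE if ok else INCOMPATIBLE


@dataclass(frozen=True)
class ParentageHypothesis:
    offspring_id: str
    parent1_id: str
    parent2_id: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.offspring_id in (self.parent1_id, self.parent2_id):
            raise ValueError("offspring cannot be its own parent")
        if self.parent1_id == UNKNOWN and self.parent2_id == UNKNOWN:
            raise ValueError("at most one parent may be UNKNOWN")


@dataclass
class ParentageVerdict:
    hypothesis: ParentageHypothesis
    n_informative: int
    n_compatible: int
    min_confidence: float
    threshold: int

    @property
    def n_mismatch(self) -> int:
        return self.n_informative - self.n_compatible

    @property
    def confidence(self) -> float | None:
        if self.n_informative == 0:
            return None  # verdict undefined without informative loci
        return self.n_compatible / self.n_informative

    @property
    def accepted(self) -> bool:
        c = self.confidence
        return c is not None and c > self.min_confidence and self.n_mismatch <= self.threshold


def evaluate_hypothesis(
    table: GenotypeTable,
    hypothesis: ParentageHypothesis,
    min_confidence: float = 0.98,
    threshold: int = 1,
) -> ParentageVerdict:
    """Score one duo/trio hypothesis over all panel markers.

    Loci where the offspring or any named parent is missing are
    uninformative. The duo rule applies when one parent is UNKNOWN.
    """
    off = table.row(hypothesis.offspring_id)
    duo_mode = UNKNOWN in (hypothesis.parent1_id, hypothesis.parent2_id)
    named = hypothesis.parent1_id if hypothesis.parent2_id == UNKNOWN else hypothesis.parent2_id
    p1 = table.row(named if duo_mode else hypothesis.parent1_id)
    p2 = None if duo_mode else table.row(hypothesis.parent2_id)
    n_inf = n_comp = 0
    for m in table.markers:
        if duo_mode:
            status = duo_compatible(off[m], p1[m])
        else:
            status = trio_compatible(off[m], p1[m], p2[m])
        if status == UNINFORMATIVE:
            continue
        n_inf += 1
        if status == COMPATIBLE:
            n_comp += 1
    return ParentageVerdict(hypothesis, n_inf, n_comp, min_confidence, threshold)


# -- collection-wide scans -------------------------------------------------


def _encode(table: GenotypeTable, accession_ids: list[str]):
    """Two allele-code arrays (n x L), -1 where missing; haploid-expanded."""
    n, L = len(accession_ids), table.n_markers
    a1 = np.full((n, L), -1, dtype=np.int64)
    a2 = np.full((n, L), -1, dtype=np.int64)
    for i, acc in enumerate(accession_ids):
        row = table.calls[table._acc_index[acc]]
        for j, c in enumerate(row):
            if c is None:
                continue
            a1[i, j] = c[0]
            a2[i, j] = c[-1]
    return a1, a2


@dataclass
class ScanHit:
    offspring_id: str
    parent1_id: str
    parent2_id: str
    n_informative: int
    n_mismatch: int
    confidence: float
    documented_match: bool
    #: all clone-group members the representative parents stand for
    parent1_group: tuple[str, ...] = ()
    parent2_group: tuple[str, ...] = ()


def scan_parentage(
    table: GenotypeTable,
    focal: list[str],
    candidates: list[str] | None = None,
    mode: str = "trio",
    min_confidence: float = 0.98,
    threshold: int = 1,
    collapse_clones: bool = True,
) -> dict[str, list[ScanHit]]:
    """Exhaustive duo/trio scan of a candidate pool for each focal accession.

    Clone collapse keeps one representative per identity group (sports are
    interchangeable as parents); each hit reports the full member list of
    the groups involved. Hits are ranked by (n_mismatch ascending,
    confidence descending, then lexicographic parent ids).
    """
    if mode not in ("trio", "duo"):
        raise ValueError(f"unknown mode {mode!r}")
    pool = list(candidates) if candidates is not None else [
        a.accession_id for a in table.accessions
    ]
    group_members: dict[str, tuple[str, ...]] = {}
    if collapse_clones:
        grouping = group_by_signature(table.subset(accession_ids=pool))
        reps = []
        for g in grouping.groups:
            rep = sorted(g.members)[0]
            reps.append(rep)
            group_members[rep] = tuple(sorted(g.members))
        pool = sorted(reps)
    else:
        group_members = {p: (p,) for p in pool}
        pool = sorted(pool)

    results: dict[str, list[ScanHit]] = {}
    for off_id in focal:
        cand = [p for p in pool if p != off_id]
        if not cand:
            results[off_id] = []
            continue
        o1, o2 = _encode(table, [off_id])
        p1m, p2m = _encode(table, cand)
        o_typed = o1[0] >= 0
        # per candidate x locus: candidate carries offspring allele 1 / 2
        has1 = (p1m == o1[0][None, :]) | (p2m == o1[0][None, :])
        has2 = (p1m == o2[0][None, :]) | (p2m == o2[0][None, :])
        typed = p1m >= 0
        acc = table.accession(off_id)
        doc = {p for p in (acc.parent1, acc.parent2) if p}
        hits: list[ScanHit] = []
        if mode == "duo":
            informative = o_typed[None, :] & typed
            compat = informative & (has1 | has2)
            n_inf = informative.sum(axis=1)
            n_comp = compat.sum(axis=1)
            for i, pid in enumerate(cand):
                v = ParentageVerdict(
                    ParentageHypothesis(off_id, pid),
                    int(n_inf[i]),
                    int(n_comp[i]),
                    min_confidence,
                    threshold,
                )
                if v.accepted:
                    hits.append(
                        ScanHit(
                            off_id,
                            pid,
                            UNKNOWN,
                            v.n_informative,
                            v.n_mismatch,
                            v.confidence,
                            pid in doc or bool(set(group_members[pid]) & doc),
                            group_members[pid],
                        )
                    )
        else:
            for i, j in combinations(range(len(cand)), 2):
                informative = o_typed & typed[i] & typed[j]
                compat = (has1[i] & has2[j]) | (has2[i] & has1[j])
                n_inf = int(informative.sum())
                n_comp = int((informative & compat).sum())
                v = ParentageVerdict(
                    ParentageHypothesis(off_id, cand[i], cand[j]),
                    n_inf,
                    n_comp,
                    min_confidence,
                    threshold,
                )
                if v.accepted:
                    pa, pb = sorted((cand[i], cand[j]))
                    hits.append(
                        ScanHit(
                            off_id,
                            pa,
                            pb,
                            n_inf,
                            v.n_mismatch,
                            v.confidence,
                            bool(
                                (set(group_members[pa]) | set(group_members[pb])) & doc
                            ),
                            group_members[pa],
                            group_members[pb],
                        )
                    )
        hits.sort(key=lambda h: (h.n_mismatch, -h.confidence, h.parent1_id, h.parent2_id))
        results[off_id] = hits
    return results
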