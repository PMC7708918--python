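"""Population-genetic statistics for co-dominant marker tables.

Implements the classical single-locus diversity suite (Na, Ne, I, Ho, He, F
with GenAlEx conventions), Weir & Cockerham's (1984) theta estimator of Fst
from a/b/c variance components, Nei's Gst as an alternative, per-locus
Fisher exact differentiation tests combined across loci by Fisher's method,
the conditional (Levene/Haldane) exact test of Hardy-Weinberg proportions,
and complete-linkage classification of genotype-frequency patterns.

Conventions
-----------
* All statistics use non-missing diploid calls only; polyploids are excluded.
* He is the uncorrected 1 - sum(p^2); the small-sample unbiased variant is
  exposed as ``uHe``.
* F = (He - Ho)/He per locus, averaged across polymorphic loci as a mean of
  ratios (the GenAlEx convention), undefined at monomorphic loci.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln

from .genotypes import CODE_D, CODE_I, GenotypeTable

# -- allele frequencies ----------------------------------------------------


@dataclass
class FreqEntry:
    freqs: dict[int, float]
    n_typed: int  # non-missing diploid individuals

    @property
    def alleles(self) -> list[int]:
        return sorted(self.freqs)


def allele_frequencies(
    table: GenotypeTable,
    grouping: dict[str, str] | None = None,
    diploids_only: bool = True,
) -> dict[str, dict[str, FreqEntry]]:
    """Per (population, marker) allele frequencies from allele counts over
    2*n_typed. ``grouping`` maps accession_id -> population; by default the
    accession's species label. Entries with zero typed individuals carry
    n_typed = 0 and an empty frequency map (flagged, excluded from means).
    """
    out: dict[str, dict[str, FreqEntry]] = {}
    for acc in table.accessions:
        if diploids_only and acc.ploidy != 2:
            continue
        pop = grouping[acc.accession_id] if grouping else (acc.species or "all")
        out.setdefault(pop, {})
    for pop in out:
        members = [
            a.accession_id
            for a in table.accessions
            if (not diploids_only or a.ploidy == 2)
            and ((grouping[a.accession_id] if grouping else (a.species or "all")) == pop)
        ]
        for m in table.markers:
            counts: Counter = Counter()
            n_typed = 0
            for acc_id in members:
                c = table.call(acc_id, m)
                if c is None:
                    continue
                n_typed += 1
                counts.update(c)
            total = sum(counts.values())
            freqs = {a: k / total for a, k in counts.items()} if total else {}
            out[pop][m] = FreqEntry(freqs, n_typed)
    return out


# -- single-locus diversity ------------------------------------------------


@dataclass
class LocusDiversity:
    marker_id: str
    Na: int
    Ne: float
    I: float
    Ho: float
    He: float
    uHe: float
    F: float | None  # undefined when He == 0
    n_typed: int


def locus_diversity(
    table: GenotypeTable,
    marker_id: str,
    accession_ids: list[str],
) -> LocusDiversity | None:
    """Diversity statistics at one marker over the given diploid accessions.

    Returns None when no individual is typed. For biallelic data the
    algebraic identity Ne = 1/(1 - He) holds by construction and is asserted
    on every call.
    """
    counts: Counter = Counter()
    n_typed = 0
    n_het = 0
    for acc_id in accession_ids:
        if table.accession(acc_id).ploidy != 2:
            continue
        c = table.call(acc_id, marker_id)
        if c is None:
            continue
        n_typed += 1
        counts.update(c)
        if len(set(c)) > 1:
            n_het += 1
    if n_typed == 0:
        return None
    total = sum(counts.values())
    p = np.array([k / total for k in counts.values()])
    sum_p2 = float(np.sum(p**2))
    he = 1.0 - sum_p2
    ne = 1.0 / sum_p2
    shannon = float(-np.sum(p * np.log(p)))
    ho = n_het / n_typed
    uhe = he * (2 * n_typed) / (2 * n_typed - 1) if n_typed > 1 else he
    f = (he - ho) / he if he > 0 else None
    assert abs(ne - 1.0 / (1.0 - he)) < 1e-9
    return LocusDiversity(marker_id, len(counts), ne, shannon, ho, he, uhe, f, n_typed)


@dataclass
class PopDiversitySummary:
    population: str
    n_loci: int
    Na: float
    Ne: float
    I: float
    Ho: float
    He: float
    uHe: float
    F: float | None
    mean_n: float


def summarize_population(
    table: GenotypeTable,
    population: str,
    accession_ids: list[str],
    markers: list[str] | None = None,
    include_monomorphic: bool = True,
) -> PopDiversitySummary:
    """Unweighted across-locus means of the per-locus statistics.

    F is averaged over loci where it is defined (polymorphic loci).
    ``include_monomorphic=False`` drops within-population monomorphic loci
    from all means.
    """
    markers = markers if markers is not None else table.markers
    per_locus = [locus_diversity(table, m, accession_ids) for m in markers]
    per_locus = [d for d in per_locus if d is not None]
    if not include_monomorphic:
        per_locus = [d for d in per_locus if d.Na > 1]
    if not per_locus:
        raise ValueError(f"population {population!r} has no typed loci")
    fs = [d.F for d in per_locus if d.F is not None]
    return PopDiversitySummary(
        population=population,
        n_loci=len(per_locus),
        Na=float(np.mean([d.Na for d in per_locus])),
        Ne=float(np.mean([d.Ne for d in per_locus])),
        I=float(np.mean([d.I for d in per_locus])),
        Ho=float(np.mean([d.Ho for d in per_locus])),
        He=float(np.mean([d.He for d in per_locus])),
        uHe=float(np.mean([d.uHe for d in per_locus])),
        F=float(np.mean(fs)) if fs else None,
        mean_n=float(np.mean([d.n_typed for d in per_locus])),
    )


def diversity_table(
    table: GenotypeTable,
    grouping: dict[str, str] | None = None,
    markers: list[str] | None = None,
    include_monomorphic: bool = True,
) -> pd.DataFrame:
    """Per-population summary rows (Table-2-style layout)."""
    pops: dict[str, list[str]] = {}
    for acc in table.accessions:
        if acc.ploidy != 2:
            continue
        pop = grouping[acc.accession_id] if grouping else (acc.species or "all")
        pops.setdefault(pop, []).append(acc.accession_id)
    rows = []
    for pop in sorted(pops):
        s = summarize_population(table, pop, pops[pop], markers, include_monomorphic)
        rows.append(
            {
                "population": s.population,
                "n": len(pops[pop]),
                "Na": s.Na,
                "Ne": s.Ne,
                "I": s.I,
                "Ho": s.Ho,
                "He": s.He,
                "uHe": s.uHe,
                "F": s.F,
            }
        )
    return pd.DataFrame(rows)


# -- Weir & Cockerham theta ------------------------------------------------


def wc_components_allele(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir-Cockerham (1984) a/b/c variance components for one allele.

    Parameters are per-population arrays: sample sizes (individuals), allele
    frequencies, and the fraction of individuals heterozygous for the
    allele. Arrays may be 1-D (one locus) or 2-D (populations x loci).
    Returns (a, b, c) per locus.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    return a, b, c


def theta_from_biallelic_arrays(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    """Multilocus theta from per-population, per-locus biallelic summaries.

    ``n``, ``p``, ``h`` have shape (n_populations, n_loci); p is the
    frequency of either one of the two alleles (the components are symmetric
    in the allele choice, so one allele per locus suffices). Loci where any
    population has no typed individuals, or nbar <= 1, are dropped.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    ok = (n > 0).all(axis=0) & (n.mean(axis=0) > 1)
    if not ok.any():
        raise ValueError("no loci with typed individuals in all populations")
    a, b, c = wc_components_allele(n[:, ok], p[:, ok], h[:, ok])
    denom = np.sum(a + b + c)
    if denom == 0:
        raise ValueError("zero total variance: all loci monomorphic")
    return float(np.sum(a) / denom)


@dataclass
class FstResult:
    estimator: str
    fst: float
    per_locus: pd.DataFrame  # marker, a, b, c (or Ht/Hs for Gst)
    n_loci: int
    p_value: float | None = None


def _pop_locus_summaries(table: GenotypeTable, members: dict[str, list[str]]):
    """Per population and marker: (n_typed, allele-count map, het-count map)."""
    out: dict[str, dict[str, tuple[int, dict, dict]]] = {}
    for pop, accs in members.items():
        out[pop] = {}
        for m in table.markers:
            counts: Counter = Counter()
            hets: Counter = Counter()
            n_typed = 0
            for acc_id in accs:
                c = table.call(acc_id, m)
                if c is None:
                    continue
                n_typed += 1
                counts.update(c)
                if len(set(c)) > 1:
                    hets.update(set(c))
            out[pop][m] = (n_typed, dict(counts), dict(hets))
    return out


def pairwise_fst(
    table: GenotypeTable,
    pop_a: list[str],
    pop_b: list[str],
    estimator: str = "WC84_theta",
    with_test: bool = False,
) -> FstResult:
    """Multilocus Fst between two accession sets.

    WC84_theta: per-locus, per-allele a/b/c components summed over alleles
    and loci, theta = sum(a)/sum(a+b+c). Nei_Gst: (Ht - Hs)/Ht with Hs the
    unweighted mean within-population expected heterozygosity and Ht from
    mean allele frequencies. Only diploid, co-typed loci contribute.
    """
    if estimator not in ("WC84_theta", "Nei_Gst"):
        raise ValueError(f"unknown estimator {estimator!r}")
    pop_a = [a for a in pop_a if table.accession(a).ploidy == 2]
    pop_b = [a for a in pop_b if table.accession(a).ploidy == 2]
    summ = _pop_locus_summaries(table, {"A": pop_a, "B": pop_b})
    rows = []
    for m in table.markers:
        na, ca, ha = summ["A"][m]
        nb, cb, hb = summ["B"][m]
        if na == 0 or nb == 0 or (na + nb) / 2 <= 1:
            continue
        fa = {al: k / (2 * na) for al, k in ca.items()}
        fb = {al: k / (2 * nb) for al, k in cb.items()}
        alleles = sorted(set(fa) | set(fb))
        if len(alleles) < 2:
            continue  # monomorphic across both: contributes nothing
        if estimator == "WC84_theta":
            a_sum = b_sum = c_sum = 0.0
            for al in alleles:
                n = np.array([na, nb], dtype=float)
                p = np.array([fa.get(al, 0.0), fb.get(al, 0.0)])
                h = np.array([ha.get(al, 0) / na, hb.get(al, 0) / nb])
                a, b, c = wc_components_allele(n, p, h)
                a_sum += float(a)
                b_sum += float(b)
                c_sum += float(c)
            rows.append({"marker": m, "a": a_sum, "b": b_sum, "c": c_sum})
        else:
            hs_a = 1.0 - sum(q**2 for q in fa.values())
            hs_b = 1.0 - sum(q**2 for q in fb.values())
            pbar = {al: (fa.get(al, 0.0) + fb.get(al, 0.0)) / 2 for al in alleles}
            ht = 1.0 - sum(q**2 for q in pbar.values())
            rows.append({"marker": m, "Hs": (hs_a + hs_b) / 2, "Ht": ht})
    if not rows:
        raise ValueError("no co-typed polymorphic loci between the two populations")
    per_locus = pd.DataFrame(rows)
    if estimator == "WC84_theta":
        denom = float((per_locus["a"] + per_locus["b"] + per_locus["c"]).sum())
        fst = float(per_locus["a"].sum() / denom)
    else:
        ht_sum = float(per_locus["Ht"].sum())
        fst = float((per_locus["Ht"] - per_locus["Hs"]).sum() / ht_sum)
    p_value = None
    if with_test:
        p_value = differentiation_test(table, pop_a, pop_b).combined_p
    return FstResult(estimator, fst, per_locus, len(per_locus), p_value)


# -- differentiation exact test -------------------------------------------


@dataclass
class DifferentiationResult:
    per_locus_p: dict[str, float]
    combined_p: float | None  # Fisher's method; None if no polymorphic locus
    n_loci: int


def differentiation_test(
    table: GenotypeTable, pop_a: list[str], pop_b: list[str]
) -> DifferentiationResult:
    """Two-sided Fisher exact test per biallelic locus on the 2x2 allele-count
    table, combined across loci as -2*sum(ln p) ~ chi-square(2L)."""
    summ = _pop_locus_summaries(
        table,
        {
            "A": [a for a in pop_a if table.accession(a).ploidy == 2],
            "B": [a for a in pop_b if table.accession(a).ploidy == 2],
        },
    )
    per_locus: dict[str, float] = {}
    for m in table.markers:
        na, ca, _ = summ["A"][m]
        nb, cb, _ = summ["B"][m]
        if na == 0 or nb == 0:
            continue
        alleles = sorted(set(ca) | set(cb))
        if len(alleles) != 2:
            continue  # monomorphic skipped; multiallelic out of test scope
        a1, a2 = alleles
        tab = [
            [ca.get(a1, 0), ca.get(a2, 0)],
            [cb.get(a1, 0), cb.get(a2, 0)],
        ]
        per_locus[m] = float(stats.fisher_exact(tab, alternative="two-sided")[1])
    if not per_locus:
        return DifferentiationResult({}, None, 0)
    ps = np.clip(np.array(list(per_locus.values())), 1e-300, 1.0)
    x2 = -2.0 * np.sum(np.log(ps))
    combined = float(stats.chi2.sf(x2, 2 * len(ps)))
    return DifferentiationResult(per_locus, combined, len(per_locus))


# -- Hardy-Weinberg exact test --------------------------------------------


def _hwe_log_prob(n_het: int, n: int, n_a: int) -> float:
    """log P(n_het | n, n_a) under the Levene/Haldane conditional
    distribution (fixed allele counts, random union of gametes)."""
    n_b = 2 * n - n_a
    n_aa = (n_a - n_het) // 2
    n_bb = (n_b - n_het) // 2
    return (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_het + 1)
        - gammaln(n_bb + 1)
        + n_het * math.log(2)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact(n_ii: int, n_id: int, n_dd: int) -> float:
    """Exact Hardy-Weinberg test p-value for biallelic genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts (same parity as observed) no more probable than the
    observed one. Monomorphic samples return 1.
    """
    if min(n_ii, n_id, n_dd) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_ii + n_id + n_dd
    if n < 1:
        raise ValueError("empty sample")
    n_a = 2 * n_ii + n_id
    n_b = 2 * n_dd + n_id
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = list(range(rare % 2, rare + 1, 2))
    logs = np.array([_hwe_log_prob(h, n, n_a) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hets.index(n_id)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_table(
    table: GenotypeTable,
    coding_markers: list[str],
    grouping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per (population, marker) exact HWE p-values and genotype counts for
    insertion/deletion-coded biallelic markers."""
    pops: dict[str, list[str]] = {}
    for acc in table.accessions:
        if acc.ploidy != 2:
            continue
        pop = grouping[acc.accession_id] if grouping else (acc.species or "all")
        pops.setdefault(pop, []).append(acc.accession_id)
    rows = []
    for pop in sorted(pops):
        for m in coding_markers:
            n_ii = n_id = n_dd = 0
            for acc_id in pops[pop]:
                c = table.call(acc_id, m)
                if c is None:
                    continue
                if c == (CODE_I, CODE_I):
                    n_ii += 1
                elif c == (CODE_D, CODE_D):
                    n_dd += 1
                elif c == (CODE_D, CODE_I):
                    n_id += 1
            if n_ii + n_id + n_dd == 0:
                continue
            rows.append(
                {
                    "population": pop,
                    "marker": m,
                    "n_II": n_ii,
                    "n_ID": n_id,
                    "n_DD": n_dd,
                    "p_value": hwe_exact(n_ii, n_id, n_dd),
                }
            )
    return pd.DataFrame(rows)


# -- genotype-frequency patterns ------------------------------------------

GENOTYPE_CLASSES = ("II", "ID", "DD")


def genotype_frequency_matrix(
    table: GenotypeTable,
    species_grouping: dict[str, str],
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Rows = markers, columns = (species-group, genotype-class) frequencies
    over insertion/deletion-coded calls; each group's three classes sum to 1
    where the group is typed."""
    markers = markers if markers is not None else table.markers
    groups = sorted(set(species_grouping.values()))
    cols = pd.MultiIndex.from_product([groups, GENOTYPE_CLASSES])
    data = np.zeros((len(markers), len(cols)))
    for mi, m in enumerate(markers):
        for gi, g in enumerate(groups):
            n_ii = n_id = n_dd = 0
            for acc in table.accessions:
                if acc.ploidy != 2 or species_grouping.get(acc.accession_id) != g:
                    continue
                c = table.call(acc.accession_id, m)
                if c == (CODE_I, CODE_I):
                    n_ii += 1
                elif c == (CODE_D, CODE_I):
                    n_id += 1
                elif c == (CODE_D, CODE_D):
                    n_dd += 1
            tot = n_ii + n_id + n_dd
            if tot:
                data[mi, 3 * gi : 3 * gi + 3] = [n_ii / tot, n_id / tot, n_dd / tot]
    return pd.DataFrame(data, index=markers, columns=cols)


@dataclass
class PatternAssignment:
    labels: dict[str, str]  # marker -> roman label
    cluster_summaries: pd.DataFrame  # mean frequency per genotype class per cluster


_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def classify_patterns(
    matrix: pd.DataFrame,
    k: int = 5,
    method: str = "complete",
    metric: str = "euclidean",
) -> PatternAssignment:
    """Cut a complete-linkage Euclidean dendrogram of the marker rows at k
    clusters and name clusters by centroid shape.

    Naming priority (documented, applied in order): the cluster with the
    highest mean heterozygote (ID) frequency is IV; among the rest, highest
    mean DD with depressed II is I; lowest mean DD is II; remaining clusters
    are labelled III, V, ... in order of first marker appearance.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of markers ({len(matrix)})")
    Z = linkage(matrix.values, method=method, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    clusters = sorted(set(raw))
    # mean frequency per genotype class, averaged over species groups
    class_means = {}
    for cl in clusters:
        sub = matrix.values[raw == cl]
        means = {}
        for ci, cls in enumerate(GENOTYPE_CLASSES):
            cols = [j for j in range(matrix.shape[1]) if j % 3 == ci]
            means[cls] = float(sub[:, cols].mean())
        class_means[cl] = means
    label_of: dict[int, str] = {}
    remaining = set(clusters)
    # IV: extreme heterozygosity everywhere
    c_iv = max(remaining, key=lambda c: class_means[c]["ID"])
    label_of[c_iv] = "IV"
    remaining.discard(c_iv)
    if remaining:
        # I: DD-skewed (high DD, low II)
        c_i = max(remaining, key=lambda c: class_means[c]["DD"] - class_means[c]["II"])
        label_of[c_i] = "I"
        remaining.discard(c_i)
    if remaining:
        # II: DD rare or absent
        c_ii = min(remaining, key=lambda c: class_means[c]["DD"])
        label_of[c_ii] = "II"
        remaining.discard(c_ii)
    spare = [r for r in _ROMAN if r not in label_of.values()]
    order = []
    for cl in raw:  # first-appearance order of leftover clusters
        if cl in remaining and cl not in order:
            order.append(cl)
    for cl, lab in zip(order, spare):
        label_of[cl] = lab
    labels = {m: label_of[cl] for m, cl in zip(matrix.index, raw)}
    summary = pd.DataFrame(
        [
            {"cluster": label_of[cl], "n_markers": int((raw == cl).sum()), **class_means[cl]}
            for cl in clusters
        ]
    ).set_index("cluster")
    return PatternAssignment(labels, summary)
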