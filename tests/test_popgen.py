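"""Diversity statistics, Weir-Cockerham theta, exact tests, patterns."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import hypergeom

from gik.genotypes import recode_biallelic
from gik.popgen import (
    allele_frequencies,
    classify_patterns,
    differentiation_test,
    diversity_table,
    genotype_frequency_matrix,
    hwe_exact,
    hwe_table,
    locus_diversity,
    pairwise_fst,
    summarize_population,
    theta_from_biallelic_arrays,
)
from tests.conftest import make_table

# -- allele frequencies ----------------------------------------------------


def test_frequencies_match_bruteforce_tally(clean_collection):
    table, truth = clean_collection
    freqs = allele_frequencies(table)
    sp = "species_A"
    accs = [a.accession_id for a in table.accessions if a.species == sp]
    for m in table.markers[:10]:
        tally: dict[int, int] = {}
        n = 0
        for acc in accs:
            c = table.call(acc, m)
            if c is None:
                continue
            n += 1
            for al in c:
                tally[al] = tally.get(al, 0) + 1
        entry = freqs[sp][m]
        assert entry.n_typed == n
        for al, k in tally.items():
            assert entry.freqs[al] == pytest.approx(k / (2 * n))
        assert sum(entry.freqs.values()) == pytest.approx(1.0, abs=1e-9)


def test_heterozygote_trio_gives_half_frequency():
    tb = make_table({"a": [(1, 2)], "b": [(1, 1)], "c": [(2, 2)]}, ["M1"])
    freqs = allele_frequencies(tb)
    assert freqs["all"]["M1"].freqs[1] == pytest.approx(0.5)


def test_all_missing_marker_flagged_with_zero_typed():
    tb = make_table({"a": [None], "b": [None]}, ["M1"])
    entry = allele_frequencies(tb)["all"]["M1"]
    assert entry.n_typed == 0 and entry.freqs == {}


# -- locus diversity -------------------------------------------------------


def test_closed_form_half_half_locus():
    tb = make_table({"a": [(1, 2)], "b": [(1, 1)], "c": [(2, 2)], "d": [(1, 2)]}, ["M1"])
    d = locus_diversity(tb, "M1", ["a", "b", "c", "d"])
    assert d.He == pytest.approx(0.5)
    assert d.Ne == pytest.approx(2.0)
    assert d.I == pytest.approx(math.log(2))
    assert d.Ho == pytest.approx(0.5)
    assert d.F == pytest.approx(0.0)


def test_monomorphic_locus_conventions():
    tb = make_table({"a": [(1, 1)], "b": [(1, 1)]}, ["M1"])
    d = locus_diversity(tb, "M1", ["a", "b"])
    assert (d.Na, d.Ne, d.He, d.I) == (1, 1.0, 0.0, 0.0)
    assert d.F is None


def test_polyploids_excluded_from_diversity():
    tb = make_table(
        {"a": [(1, 2)], "b": [(1, 2)], "t4": [(1, 2)]},
        ["M1"],
        ploidy={"t4": 4},
    )
    d = locus_diversity(tb, "M1", ["a", "b", "t4"])
    assert d.n_typed == 2


def test_population_means_are_unweighted_and_F_skips_monomorphic(clean_collection):
    table, _ = clean_collection
    accs = [a.accession_id for a in table.accessions if a.species == "species_G"][:10]
    s = summarize_population(table, "species_G", accs)
    per_locus = [locus_diversity(table, m, accs) for m in table.markers]
    per_locus = [d for d in per_locus if d is not None]
    assert s.He == pytest.approx(np.mean([d.He for d in per_locus]))
    fs = [d.F for d in per_locus if d.F is not None]
    assert s.F == pytest.approx(np.mean(fs))
    assert len(fs) < len(per_locus) or all(d.Na > 1 for d in per_locus)


def test_diversity_table_bounds(clean_collection):
    table, _ = clean_collection
    df = diversity_table(table)
    assert set(df["population"]) == {f"species_{c}" for c in "ABCDEFG"}
    assert ((df["Ho"] >= 0) & (df["Ho"] <= 1)).all()
    assert ((df["He"] >= 0) & (df["He"] < 1)).all()
    assert (df["Ne"] <= df["Na"] + 1e-9).all()
    assert (df["I"] >= 0).all()


# -- Weir-Cockerham theta --------------------------------------------------


def oracle_theta(pops):
    """Independent transcription of the 1984 a/b/c component formulas,
    written directly from per-population genotype counts.

    ``pops``: list of (n_II, n_ID, n_DD) per population. Biallelic.
    """
    r = len(pops)
    n = np.array([sum(p) for p in pops], dtype=float)
    p_freq = np.array([(2 * a + h) / (2 * t) for (a, h, _), t in zip(pops, n)])
    h_freq = np.array([h / t for (_, h, _), t in zip(pops, n)])
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p_freq).sum() / (r * nbar)
    s2 = (n * (p_freq - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h_freq).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def table_from_counts(counts_a, counts_b):
    rows = {}
    for pop, (nii, nid, ndd) in (("A", counts_a), ("B", counts_b)):
        i = 0
        for geno, k in zip([(2, 2), (1, 2), (1, 1)], (nii, nid, ndd)):
            for _ in range(k):
                rows[f"{pop}{i}"] = [geno]
                i += 1
    species = {k: k[0] for k in rows}
    return make_table(rows, ["M1"], species=species)


def test_theta_matches_independent_component_transcription():
    counts_a, counts_b = (12, 30, 8), (3, 10, 37)
    tb = table_from_counts(counts_a, counts_b)
    ids_a = [a.accession_id for a in tb.accessions if a.species == "A"]
    ids_b = [a.accession_id for a in tb.accessions if a.species == "B"]
    res = pairwise_fst(tb, ids_a, ids_b)
    assert res.fst == pytest.approx(oracle_theta([counts_a, counts_b]), abs=1e-12)


def test_theta_one_when_populations_fixed_for_alternative_alleles():
    tb = table_from_counts((20, 0, 0), (0, 0, 20))
    ids_a = [a.accession_id for a in tb.accessions if a.species == "A"]
    ids_b = [a.accession_id for a in tb.accessions if a.species == "B"]
    assert pairwise_fst(tb, ids_a, ids_b).fst == pytest.approx(1.0)


def test_theta_near_zero_for_identical_frequencies(rng):
    """Two samples from one panmictic pool: |theta| < 0.02 at n=200."""
    n, L = 200, 80
    p = rng.uniform(0.2, 0.8, size=L)
    thetas = []
    for _ in range(10):
        ns, ps, hs = [], [], []
        for _pop in range(2):
            dose = rng.binomial(2, p, size=(n, L))
            ns.append(np.full(L, n))
            ps.append((dose.sum(axis=0)) / (2 * n))
            hs.append((dose == 1).mean(axis=0))
        thetas.append(theta_from_biallelic_arrays(np.array(ns), np.array(ps), np.array(hs)))
    assert abs(np.mean(thetas)) < 0.02


def test_nei_gst_agrees_in_sign_and_scale():
    tb = table_from_counts((12, 30, 8), (3, 10, 37))
    ids_a = [a.accession_id for a in tb.accessions if a.species == "A"]
    ids_b = [a.accession_id for a in tb.accessions if a.species == "B"]
    th = pairwise_fst(tb, ids_a, ids_b).fst
    gst = pairwise_fst(tb, ids_a, ids_b, estimator="Nei_Gst").fst
    # Gst is downward-biased relative to theta in small samples; same sign
    # and order of magnitude is the meaningful agreement here
    assert 0 < gst < th < 4 * gst


def test_fst_errors_without_cotyped_loci():
    tb = make_table(
        {"a": [(1, 2), None], "b": [None, (1, 2)]},
        ["M1", "M2"],
        species={"a": "A", "b": "B"},
    )
    with pytest.raises(ValueError):
        pairwise_fst(tb, ["a"], ["b"])


# -- differentiation exact test -------------------------------------------


def test_identical_counts_give_p_one():
    tb = table_from_counts((5, 10, 5), (5, 10, 5))
    ids_a = [a.accession_id for a in tb.accessions if a.species == "A"]
    ids_b = [a.accession_id for a in tb.accessions if a.species == "B"]
    res = differentiation_test(tb, ids_a, ids_b)
    assert res.per_locus_p["M1"] == pytest.approx(1.0)
    assert res.combined_p == pytest.approx(1.0)


def test_fixed_contrast_equals_hypergeometric_tail():
    """20 II vs 20 DD accessions: Fisher p equals the enumeration tail."""
    tb = table_from_counts((20, 0, 0), (0, 0, 20))
    ids_a = [a.accession_id for a in tb.accessions if a.species == "A"]
    ids_b = [a.accession_id for a in tb.accessions if a.species == "B"]
    res = differentiation_test(tb, ids_a, ids_b)
    # 2x2 table [[40,0],[0,40]]: two-sided Fisher = sum of both extreme tables
    rv = hypergeom(80, 40, 40)
    expected = sum(rv.pmf(k) for k in range(81) if rv.pmf(k) <= rv.pmf(40) * (1 + 1e-9))
    assert res.per_locus_p["M1"] == pytest.approx(expected, rel=1e-6)


def test_combined_p_monotone_in_per_locus_p():
    from scipy.stats import chi2

    def combine(ps):
        return chi2.sf(-2 * np.sum(np.log(ps)), 2 * len(ps))

    base = [0.5, 0.5, 0.5]
    lowered = [0.5, 0.1, 0.5]
    assert combine(lowered) < combine(base)
    assert combine([1.0, 1.0]) == pytest.approx(1.0)


def test_no_polymorphic_locus_reports_undefined():
    tb = make_table({"a": [(1, 1)], "b": [(1, 1)]}, ["M1"], species={"a": "A", "b": "B"})
    res = differentiation_test(tb, ["a"], ["b"])
    assert res.combined_p is None and res.n_loci == 0


# -- Hardy-Weinberg exact test --------------------------------------------


def hwe_oracle(n_ii, n_id, n_dd):
    """Full enumeration of the Levene/Haldane conditional distribution."""
    n = n_ii + n_id + n_dd
    n_a = 2 * n_ii + n_id
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0

    def prob(h):
        naa, nbb = (n_a - h) // 2, (n_b - h) // 2
        return math.exp(
            gammaln(n + 1)
            - gammaln(naa + 1)
            - gammaln(h + 1)
            - gammaln(nbb + 1)
            + h * math.log(2)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    hets = range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)
    probs = {h: prob(h) for h in hets}
    tot = sum(probs.values())
    obs = probs[n_id] / tot
    return sum(p / tot for p in probs.values() if p / tot <= obs * (1 + 1e-9))


def test_hwe_exact_equals_enumeration_for_all_small_samples():
    for n in range(1, 11):
        for n_ii in range(n + 1):
            for n_id in range(n - n_ii + 1):
                n_dd = n - n_ii - n_id
                assert hwe_exact(n_ii, n_id, n_dd) == pytest.approx(
                    hwe_oracle(n_ii, n_id, n_dd), abs=1e-10
                ), (n_ii, n_id, n_dd)


def test_hwe_trivial_and_errors():
    assert hwe_exact(5, 0, 0) == 1.0
    assert hwe_exact(1, 0, 1) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        hwe_exact(-1, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact(0, 0, 0)


def test_hwe_type_one_error_not_above_nominal(rng):
    """Super-uniformity under the null: exact-test rejections at alpha=0.05
    stay at or below 5% over many HWE samples."""
    reps, n = 4000, 25
    p = rng.uniform(0.2, 0.8, size=reps)
    dose = rng.binomial(2, p[None, :].repeat(n, axis=0))
    n_ii = (dose == 2).sum(axis=0)
    n_id = (dose == 1).sum(axis=0)
    n_dd = (dose == 0).sum(axis=0)
    pvals = np.array([hwe_exact(a, b, c) for a, b, c in zip(n_ii, n_id, n_dd)])
    assert (pvals <= 0.05).mean() <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / reps)


def test_hwe_table_counts_sum_to_typed(clean_collection):
    table, _ = clean_collection
    coding = recode_biallelic(table)
    df = hwe_table(coding.table, coding.biallelic_markers)
    assert ((df["p_value"] > 0) & (df["p_value"] <= 1)).all()
    row = df.iloc[0]
    accs = [
        a.accession_id
        for a in coding.table.accessions
        if (a.species or "all") == row["population"]
    ]
    n_typed = sum(1 for a in accs if coding.table.call(a, row["marker"]) is not None)
    assert row[["n_II", "n_ID", "n_DD"]].sum() == n_typed


# -- genotype-frequency patterns ------------------------------------------


def test_frequency_matrix_rows_sum_to_one(clean_collection):
    table, _ = clean_collection
    coding = recode_biallelic(table)
    grouping = {a.accession_id: a.species for a in coding.table.accessions}
    gfm = genotype_frequency_matrix(coding.table, grouping, coding.biallelic_markers)
    for g in {c[0] for c in gfm.columns}:
        sums = gfm[g].sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)


def _block_matrix():
    """Five marker groups with archetypal genotype-frequency profiles over
    two species groups (columns II, ID, DD per group)."""
    profiles = {
        "I": [0.07, 0.21, 0.72, 0.02, 0.18, 0.80],  # DD-skewed
        "II": [0.60, 0.38, 0.02, 0.70, 0.30, 0.00],  # DD rare
        "III": [0.30, 0.45, 0.25, 0.28, 0.47, 0.25],
        "IV": [0.05, 0.90, 0.05, 0.08, 0.85, 0.07],  # extreme heterozygosity
        "V": [0.33, 0.33, 0.34, 0.30, 0.40, 0.30],
    }
    rows, labels = [], {}
    for lab, prof in profiles.items():
        for i in range(3):
            m = f"{lab}_{i}"
            rows.append(pd.Series(prof, name=m))
            labels[m] = lab
    cols = pd.MultiIndex.from_product([["grpA", "grpB"], ["II", "ID", "DD"]])
    mat = pd.DataFrame(rows)
    mat.columns = cols
    return mat, labels


def test_block_matrix_recovers_archetypal_labels():
    mat, truth = _block_matrix()
    res = classify_patterns(mat, k=5)
    assert res.labels[f"I_0"] == "I"
    assert res.labels[f"II_0"] == "II"
    assert res.labels[f"IV_0"] == "IV"
    for lab in ("I", "II", "III", "IV", "V"):
        # each planted block lands in exactly one cluster
        assert len({res.labels[f"{lab}_{i}"] for i in range(3)}) == 1
    assert res.cluster_summaries.loc["IV", "ID"] > 0.8


def test_toy_partition_matches_exhaustive_min_diameter():
    """On 12 well-separated rows the k=3 complete-linkage cut equals the
    globally optimal minimum-max-diameter partition (brute force over all
    assignments)."""
    rng = np.random.default_rng(2)
    centers = np.array([[0.0] * 6, [5.0] * 6, [10.0] * 6])
    X = np.vstack([c + rng.normal(0, 0.1, size=(4, 6)) for c in centers])
    mat = pd.DataFrame(X, index=[f"m{i}" for i in range(12)])
    mat.columns = pd.MultiIndex.from_product([["g1", "g2"], ["II", "ID", "DD"]])
    res = classify_patterns(mat, k=3)
    got = {}
    for m, lab in res.labels.items():
        got.setdefault(lab, set()).add(int(m[1:]))

    def diameter(idx):
        idx = list(idx)
        return max(
            (np.linalg.norm(X[i] - X[j]) for i, j in combinations(idx, 2)), default=0.0
        )

    best, best_score = None, np.inf
    for assign in np.ndindex(*([3] * 11)):  # first point pinned to cluster 0
        full = (0,) + assign
        parts = [set(np.where(np.array(full) == c)[0]) for c in range(3)]
        if any(not p for p in parts):
            continue
        score = max(diameter(p) for p in parts)
        if score < best_score:
            best_score, best = score, parts
    assert sorted(map(frozenset, got.values())) == sorted(map(frozenset, best))


def test_k_bounds_checked():
    mat, _ = _block_matrix()
    with pytest.raises(ValueError):
        classify_patterns(mat, k=1)
    with pytest.raises(ValueError):
        classify_patterns(mat, k=100)
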