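"""SV parsing, filtering, panel spacing and multiplex packing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gik.sv import (
    MarkerDef,
    SVRecord,
    assign_product_sizes,
    design_multiplex,
    filter_indel_candidates,
    read_sv_vcf,
    select_panel,
    summarize_svs,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">
##FILTER=<ID=LowQual,Description="low quality">
##contig=<ID=chr1,length=10000000>
##contig=<ID=chr5,length=10000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(tmp_path, body: str):
    p = tmp_path / "svs.vcf"
    p.write_text(VCF_HEADER + body)
    return str(p)


def test_del_record_parses_with_end_derived_length(tmp_path):
    path = write_vcf(tmp_path, "chr1\t100\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=300\n")
    (rec,) = read_sv_vcf(path)
    assert rec.svtype == "DEL" and rec.length == 200 and rec.quality_pass


def test_ins_length_from_svlen_despite_pos_eq_end(tmp_path):
    path = write_vcf(tmp_path, "chr1\t500\t.\tN\t<INS>\t.\tPASS\tSVTYPE=INS;END=500;SVLEN=120\n")
    (rec,) = read_sv_vcf(path)
    assert rec.svtype == "INS" and rec.length == 120


def test_bnd_mates_resolve_to_ctx_and_itx_once(tmp_path):
    body = (
        "chr1\t100\tbnd1\tN\tN[chr5:200[\t.\tPASS\tSVTYPE=BND\n"
        "chr5\t200\tbnd2\tN\t]chr1:100]N\t.\tPASS\tSVTYPE=BND\n"
        "chr1\t400\tbnd3\tN\tN[chr1:900[\t.\tPASS\tSVTYPE=BND\n"
        "chr1\t900\tbnd4\tN\t]chr1:400]N\t.\tPASS\tSVTYPE=BND\n"
    )
    recs = read_sv_vcf(write_vcf(tmp_path, body))
    assert sorted(r.svtype for r in recs) == ["CTX", "ITX"]
    itx = next(r for r in recs if r.svtype == "ITX")
    assert (itx.start, itx.end) == (400, 900)


def test_legacy_tra_with_chr2_classified_by_chromosome(tmp_path):
    body = "chr1\t100\t.\tN\t<TRA>\t.\tPASS\tSVTYPE=TRA;CHR2=chr5;END=200\n"
    (rec,) = read_sv_vcf(write_vcf(tmp_path, body))
    assert rec.svtype == "CTX" and rec.chrom2 == "chr5"


def test_lowqual_filter_flag_respected(tmp_path):
    body = "chr1\t100\t.\tN\t<DEL>\t.\tLowQual\tSVTYPE=DEL;END=300\n"
    (rec,) = read_sv_vcf(write_vcf(tmp_path, body))
    assert not rec.quality_pass
    assert filter_indel_candidates([rec]) == []
    assert filter_indel_candidates([rec], require_pass=False) == [rec]


def test_synthetic_vcf_tally_matches_generator_log(tmp_path, rng):
    """Round-trip: write a VCF of known composition, re-read, compare tallies."""
    truth = {"DEL": 7, "INS": 5, "INV": 3}
    lines = []
    pos = 100
    for t, k in truth.items():
        for _ in range(k):
            ln = int(rng.integers(60, 800))
            if t == "INS":
                lines.append(f"chr1\t{pos}\t.\tN\t<INS>\t.\tPASS\tSVTYPE=INS;END={pos};SVLEN={ln}")
            else:
                lines.append(f"chr1\t{pos}\t.\tN\t<{t}>\t.\tPASS\tSVTYPE={t};END={pos + ln}")
            pos += 2000
    recs = read_sv_vcf(write_vcf(tmp_path, "\n".join(lines) + "\n"))
    summary = summarize_svs(recs)
    assert {k: v for k, v in summary["counts"].items() if v} == truth
    assert summary["n_records"] == sum(truth.values()) == sum(summary["counts"].values())


def test_summary_counts_and_in_range_fraction():
    recs = [
        SVRecord("chr1", 100, 300, "DEL", 200),
        SVRecord("chr1", 500, 1000, "DEL", 500),
        SVRecord("chr1", 700, 700, "INS", 60),
    ]
    s = summarize_svs(recs)
    assert s["counts"] == {"DEL": 2, "INS": 1, "INV": 0, "ITX": 0, "CTX": 0}
    assert s["fraction_in_range"]["DEL"] == 0.5
    assert s["fraction_in_range"]["INS"] == 1.0
    assert summarize_svs([])["counts"]["DEL"] == 0


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["DEL", "INS", "INV"]),
            st.integers(min_value=1, max_value=1000),
            st.booleans(),
        ),
        max_size=60,
    )
)
@settings(deadline=None, max_examples=50)
def test_filter_equals_bruteforce_and_is_idempotent(items):
    recs = [
        SVRecord("chr1", 10, 10 + ln if t != "INS" else 10, t, ln, qp)
        for t, ln, qp in items
    ]
    got = filter_indel_candidates(recs)
    oracle = [r for r in recs if r.svtype in ("DEL", "INS") and 50 <= r.length <= 400 and r.quality_pass]
    assert got == oracle
    assert filter_indel_candidates(got) == got


def test_filter_bounds_inclusive_and_bad_args():
    edge = SVRecord("chr1", 10, 410, "DEL", 400)
    assert filter_indel_candidates([edge]) == [edge]
    with pytest.raises(ValueError):
        filter_indel_candidates([], min_len=500, max_len=100)


# -- panel selection -------------------------------------------------------


def _min_gap(positions):
    s = sorted(positions)
    return min(b - a for a, b in zip(s, s[1:]))


def brute_force_optimum(positions, k):
    return max(
        _min_gap(sub) for sub in itertools.combinations(positions, k)
    )


def make_candidates(positions, chrom="chr1"):
    return [SVRecord(chrom, int(p), int(p) + 100, "DEL", 100) for p in positions]


def test_small_chromosome_keeps_everything():
    panel = select_panel(make_candidates([100, 200, 300]), per_chrom=10)
    assert len(panel) == 3


def test_even_spacing_reaches_exhaustive_optimum():
    positions = [i * 1_000_000 for i in range(20)]
    panel = select_panel(make_candidates(positions), per_chrom=10)
    got = _min_gap([m.position for m in panel])
    assert got == brute_force_optimum(positions, 10)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_random_instances_reach_exhaustive_optimum(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(12, 21))
    k = int(rng.integers(3, min(n, 11)))
    positions = sorted(rng.choice(50_000_000, size=n, replace=False).tolist())
    panel = select_panel(make_candidates(positions), per_chrom=k)
    assert len(panel) == k
    assert _min_gap([m.position for m in panel]) == brute_force_optimum(positions, k)


def test_per_chrom_one_takes_midpoint_candidate_tie_to_smaller():
    # span midpoint 500; 400 and 600 tie -> smaller coordinate wins
    panel = select_panel(make_candidates([0, 400, 600, 1000]), per_chrom=1)
    assert [m.position for m in panel] == [400]


def test_marker_ids_follow_naming_convention():
    positions = [1_000_000, 2_000_000, 3_000_000]
    panel = select_panel(make_candidates(positions, chrom="chr7"), per_chrom=2)
    assert all(m.marker_id.startswith("C07") for m in panel)
    serials = sorted(int(m.marker_id[3:]) for m in panel)
    assert serials == [1, 3]  # position rank among candidates, extremes kept


def test_empty_chromosome_warns_and_is_omitted():
    panel = select_panel(make_candidates([100, 900]), per_chrom=2)
    assert {m.chrom for m in panel} == {"chr1"}


# -- multiplex packing -----------------------------------------------------


def check_conflicts(groups, markers, size_gap):
    """Independent O(n^2) validator: same group + same dye => padded
    product-size intervals disjoint."""
    by_id = {m.marker_id: m for m in markers}
    for grp in groups:
        for (ida, dya), (idb, dyb) in itertools.combinations(grp.members, 2):
            if dya != dyb:
                continue
            (la, ha), (lb, hb) = by_id[ida].size_range, by_id[idb].size_range
            assert ha + size_gap < lb or hb + size_gap < la, (
                f"{ida}/{idb} overlap in group {grp.group_id} dye {dya}"
            )


def mk_marker(i, lo, hi):
    return MarkerDef(f"M{i:03d}", "chr1", 1000 * (i + 1), hi - lo, allele_sizes=(hi, lo))


def test_two_overlapping_markers_one_dye_split_into_two_groups():
    ms = [mk_marker(0, 100, 200), mk_marker(1, 150, 260)]
    groups = design_multiplex(ms, dyes=("FAM",), max_group_size=1)
    assert len(groups) == 2


def test_disjoint_markers_share_a_group_and_a_dye():
    ms = [mk_marker(0, 100, 150), mk_marker(1, 200, 260)]
    groups = design_multiplex(ms, dyes=("FAM",), size_gap=20)
    assert len(groups) == 1 and len(groups[0].members) == 2


def test_marker_outside_detectable_range_rejected():
    with pytest.raises(ValueError, match="detectable range"):
        design_multiplex([mk_marker(0, 100, 600)])


def test_every_marker_assigned_exactly_once_and_conflict_free(rng):
    ms = []
    for i in range(30):
        lo = int(rng.integers(60, 380))
        ms.append(mk_marker(i, lo, lo + int(rng.integers(50, 120))))
    groups = design_multiplex(ms, size_gap=20, max_group_size=24)
    assigned = [mid for g in groups for mid, _ in g.members]
    assert sorted(assigned) == sorted(m.marker_id for m in ms)
    assert all(len(g.members) <= 24 for g in groups)
    check_conflicts(groups, ms, size_gap=20)


def test_assign_product_sizes_respects_indel_length(rng):
    panel = select_panel(make_candidates([1_000_000, 9_000_000]), per_chrom=2)
    sized = assign_product_sizes(panel, rng=rng)
    for m in sized:
        hi, lo = max(m.allele_sizes), min(m.allele_sizes)
        assert hi - lo == m.indel_length
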