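"""Structural-variant triage and InDel marker panel design.

Consumes Delly-style SV calls (VCF with SVTYPE/END/SVLEN/CHR2, or BND mate
pairs), summarises the five SV classes (DEL, INS, INV, ITX, CTX), filters
InDel candidates by length, selects a genome-spaced panel, and packs markers
into fluorescent multiplex PCR groups.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

SV_TYPES = ("DEL", "INS", "INV", "ITX", "CTX")
DYES = ("FAM", "HEX", "NED", "PET")

#: 1-based chromosome-number pattern in labels like "chr7", "Chr07", "7"
_CHROM_NUM = re.compile(r"(\d+)")

#: ALT breakend notation, e.g. N[chr5:100[ or ]chr5:100]N
_BND_ALT = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


class VCFParseError(ValueError):
    """Raised for malformed SV records, with the offending record named."""


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant call.

    ``length`` is the inserted length for INS, ``end - start`` for DEL/INV,
    and ``None`` for translocations, whose span is not a fragment length.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    length: int | None
    quality_pass: bool = True
    chrom2: str | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.svtype != "CTX" and self.end < self.start:
            raise ValueError(f"end < start for {self.svtype} at {self.chrom}:{self.start}")
        if self.svtype in ("DEL", "INS", "INV") and (self.length is None or self.length <= 0):
            raise ValueError(f"{self.svtype} record must have positive length")


@dataclass
class MarkerDef:
    """A panel marker: an InDel locus with two expected PCR product sizes.

    ``allele_sizes`` is (insertion-allele size, deletion-allele size) in bp;
    the two differ by the InDel length. Dye and multiplex group are assigned
    by :func:`design_multiplex`.
    """

    marker_id: str
    chrom: str
    position: int
    indel_length: int
    allele_sizes: tuple[int, int] | None = None
    dye: str | None = None
    multiplex_group: int | None = None

    @property
    def size_range(self) -> tuple[int, int]:
        if self.allele_sizes is None:
            raise ValueError(f"{self.marker_id}: product sizes not assigned")
        return (min(self.allele_sizes), max(self.allele_sizes))


@dataclass
class MultiplexGroup:
    group_id: int
    members: list[tuple[str, str]] = field(default_factory=list)  # (marker_id, dye)
    size_gap: int = 20


def _svtype_of(rec: pysam.VariantRecord) -> str | None:
    info = rec.info
    return str(info["SVTYPE"]) if "SVTYPE" in info else None


def _bnd_mate(rec: pysam.VariantRecord) -> tuple[str, int] | None:
    """Mate coordinate of a breakend, from the ALT string or CHR2/END."""
    for alt in rec.alts or ():
        m = _BND_ALT.search(alt)
        if m:
            return m.group(1), int(m.group(2))
    if "CHR2" in rec.info:
        chr2 = rec.info["CHR2"]
        if isinstance(chr2, tuple):
            chr2 = chr2[0]
        end = rec.stop
        if "POS2" in rec.info:
            end = int(rec.info["POS2"])
        return str(chr2), int(end)
    return None


def _indel_length(rec: pysam.VariantRecord, svtype: str) -> int:
    if svtype == "INS":
        if "SVLEN" in rec.info:
            svlen = rec.info["SVLEN"]
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            return abs(int(svlen))
        if "INSLEN" in rec.info:
            return int(rec.info["INSLEN"])
        # fall back to inserted sequence length when given literally
        if rec.alts and not rec.alts[0].startswith("<"):
            return max(len(rec.alts[0]) - len(rec.ref or ""), 1)
        raise VCFParseError(f"INS at {rec.chrom}:{rec.pos} has no SVLEN/INSLEN")
    return rec.stop - rec.pos


def read_sv_vcf(path: str) -> list[SVRecord]:
    """Parse an SV VCF into the five-class vocabulary.

    Non-BND records map directly through SVTYPE (legacy Delly ``TRA`` is
    classified by CHR2 into ITX/CTX). BND mate pairs are resolved to ITX when
    both breakends share a chromosome, CTX otherwise, and each pair is
    emitted once. BND records without a resolvable mate are skipped and
    counted in a single warning.
    """
    records: list[SVRecord] = []
    seen_pairs: set[frozenset] = set()
    n_unresolved = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            svtype = _svtype_of(rec)
            if svtype is None:
                raise VCFParseError(f"record at {rec.chrom}:{rec.pos} lacks SVTYPE")
            qpass = (not rec.filter.keys()) or ("PASS" in rec.filter.keys())
            if svtype in ("DEL", "INS", "INV"):
                length = _indel_length(rec, svtype)
                end = rec.pos if svtype == "INS" else rec.stop
                records.append(
                    SVRecord(rec.chrom, rec.pos, end, svtype, length, qpass)
                )
            elif svtype in ("BND", "TRA", "ITX", "CTX"):
                mate = _bnd_mate(rec)
                if mate is None and svtype in ("ITX", "CTX"):
                    mate = (rec.chrom, rec.stop)
                if mate is None:
                    n_unresolved += 1
                    continue
                chr2, pos2 = mate
                key = frozenset([(rec.chrom, rec.pos), (chr2, pos2)])
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                if chr2 == rec.chrom:
                    lo, hi = sorted((rec.pos, pos2))
                    records.append(SVRecord(rec.chrom, lo, hi, "ITX", None, qpass))
                else:
                    records.append(
                        SVRecord(rec.chrom, rec.pos, pos2, "CTX", None, qpass, chrom2=chr2)
                    )
            else:
                raise VCFParseError(
                    f"unsupported SVTYPE {svtype!r} at {rec.chrom}:{rec.pos}"
                )
    if n_unresolved:
        warnings.warn(f"skipped {n_unresolved} breakend record(s) without a resolvable mate")
    return records


def summarize_svs(
    records: list[SVRecord],
    bin_width: int = 50,
    max_binned_length: int = 1000,
    in_range: tuple[int, int] = (50, 400),
) -> dict:
    """Counts per SV class plus DEL/INS length histograms.

    Returns a dict with ``counts`` (all five classes, summing to the number
    of records), ``length_hist`` per InDel type (fixed-width bins up to
    ``max_binned_length`` plus an overflow bin), and ``fraction_in_range``
    per InDel type for the ``in_range`` window (inclusive).
    """
    counts = {t: 0 for t in SV_TYPES}
    for r in records:
        counts[r.svtype] += 1
    edges = list(range(0, max_binned_length + bin_width, bin_width))
    summary: dict = {"counts": counts, "n_records": len(records), "bin_edges": edges}
    hist: dict[str, list[int]] = {}
    frac: dict[str, float | None] = {}
    lo, hi = in_range
    for t in ("DEL", "INS"):
        lengths = [r.length for r in records if r.svtype == t and r.length is not None]
        bins = [0] * (len(edges) - 1) + [0]  # trailing overflow bin
        for ln in lengths:
            if ln >= max_binned_length:
                bins[-1] += 1
            else:
                bins[ln // bin_width] += 1
        hist[t] = bins
        frac[t] = (
            sum(1 for ln in lengths if lo <= ln <= hi) / len(lengths) if lengths else None
        )
    summary["length_hist"] = hist
    summary["fraction_in_range"] = frac
    return summary


def filter_indel_candidates(
    records: list[SVRecord],
    min_len: int = 50,
    max_len: int = 400,
    require_pass: bool = True,
) -> list[SVRecord]:
    """Keep DEL/INS records with min_len <= length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [
        r
        for r in records
        if r.svtype in ("DEL", "INS")
        and r.length is not None
        and min_len <= r.length <= max_len
        and (r.quality_pass or not require_pass)
    ]


def _chrom_number(chrom: str, fallback: int) -> int:
    m = _CHROM_NUM.search(chrom)
    return int(m.group(1)) if m else fallback


def _max_min_gap_subset(positions: list[int], k: int) -> list[int]:
    """Indices (into sorted positions) of k points maximizing the minimum gap.

    Exact: the feasibility of a minimum gap d (can k points be chosen pairwise
    >= d apart?) is monotone in d and checkable by a leftmost-first greedy
    sweep, so a binary search over achievable gap values finds the optimum;
    the greedy sweep at the optimal gap returns the smallest-coordinate
    selection, which is the declared tie rule.
    """
    n = len(positions)
    if k >= n:
        return list(range(n))

    def greedy(d: int) -> list[int]:
        picked = [0]
        for i in range(1, n):
            if positions[i] - positions[picked[-1]] >= d:
                picked.append(i)
                if len(picked) == k:
                    break
        return picked

    gaps = sorted({positions[j] - positions[i] for i in range(n) for j in range(i + 1, n)})
    lo, hi = 0, len(gaps) - 1
    best = 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if len(greedy(gaps[mid])) >= k:
            best = gaps[mid]
            lo = mid + 1
        else:
            hi = mid - 1
    return greedy(best)


def select_panel(candidates: list[SVRecord], per_chrom: int = 10) -> list[MarkerDef]:
    """Select up to ``per_chrom`` markers per chromosome, spaced as evenly as
    the candidates allow (the chosen subset maximizes its minimum pairwise
    physical distance; per_chrom=1 takes the candidate nearest the midpoint
    of the candidate span, ties to the smaller coordinate).

    Marker ids follow the C<chrom:02d><serial:03d> convention, with serials
    given by position rank among that chromosome's candidates.
    """
    if per_chrom < 1:
        raise ValueError("per_chrom must be >= 1")
    by_chrom: dict[str, list[SVRecord]] = {}
    for r in candidates:
        by_chrom.setdefault(r.chrom, []).append(r)

    panel: list[MarkerDef] = []
    for ci, chrom in enumerate(sorted(by_chrom), start=1):
        recs = sorted(by_chrom[chrom], key=lambda r: r.start)
        if not recs:
            warnings.warn(f"chromosome {chrom} has no candidates; omitted")
            continue
        positions = [r.start for r in recs]
        if per_chrom == 1:
            mid = (positions[0] + positions[-1]) / 2.0
            best_i = min(range(len(recs)), key=lambda i: (abs(positions[i] - mid), positions[i]))
            chosen = [best_i]
        else:
            chosen = _max_min_gap_subset(positions, per_chrom)
        cnum = _chrom_number(chrom, ci)
        for i in chosen:
            rec = recs[i]
            serial = i + 1  # rank by position among this chromosome's candidates
            panel.append(
                MarkerDef(
                    marker_id=f"C{cnum:02d}{serial:03d}",
                    chrom=chrom,
                    position=rec.start,
                    indel_length=int(rec.length or 0),
                )
            )
    return panel


def assign_product_sizes(
    markers: list[MarkerDef],
    flank: int = 60,
    rng: np.random.Generator | None = None,
    jitter: int = 40,
) -> list[MarkerDef]:
    """Attach expected PCR product sizes: deletion allele = 2*flank (+ optional
    jitter emulating primer placement), insertion allele = deletion + InDel
    length. Markers that already carry sizes are left untouched.
    """
    out = []
    for m in markers:
        if m.allele_sizes is not None:
            out.append(m)
            continue
        base = 2 * flank
        if rng is not None and jitter > 0:
            base += int(rng.integers(0, jitter + 1))
        out.append(replace(m, allele_sizes=(base + m.indel_length, base)))
    return out


def design_multiplex(
    markers: list[MarkerDef],
    dyes: tuple[str, ...] = DYES,
    size_gap: int = 20,
    max_group_size: int = 24,
    detectable_range: tuple[int, int] = (50, 500),
) -> list[MultiplexGroup]:
    """Pack markers into multiplex PCR groups by first-fit-decreasing span.

    Within one (group, dye) channel, product-size intervals padded by
    ``size_gap`` must be pairwise disjoint. Markers are placed in decreasing
    order of their own size span (ties by marker id) into the first group and
    dye that accepts them; a marker whose products fall outside
    ``detectable_range`` is rejected.
    """
    if size_gap < 0 or max_group_size < 1:
        raise ValueError("size_gap must be >= 0 and max_group_size >= 1")
    lo_d, hi_d = detectable_range
    for m in markers:
        lo, hi = m.size_range
        if lo < lo_d or hi > hi_d:
            raise ValueError(
                f"{m.marker_id}: product sizes {m.allele_sizes} outside the "
                f"detectable range {detectable_range}"
            )
    order = sorted(markers, key=lambda m: (-(m.size_range[1] - m.size_range[0]), m.marker_id))
    groups: list[MultiplexGroup] = []
    # intervals[(gidx, dye)] -> list of (lo, hi)
    intervals: dict[tuple[int, str], list[tuple[int, int]]] = {}

    def fits(gidx: int, dye: str, lo: int, hi: int) -> bool:
        for olo, ohi in intervals.get((gidx, dye), ()):
            if lo <= ohi + size_gap and olo <= hi + size_gap:
                return False
        return True

    for m in order:
        lo, hi = m.size_range
        placed = False
        for gidx, grp in enumerate(groups):
            if len(grp.members) >= max_group_size:
                continue
            for dye in dyes:
                if fits(gidx, dye, lo, hi):
                    grp.members.append((m.marker_id, dye))
                    intervals.setdefault((gidx, dye), []).append((lo, hi))
                    m.dye, m.multiplex_group = dye, grp.group_id
                    placed = True
                    break
            if placed:
                break
        if not placed:
            grp = MultiplexGroup(group_id=len(groups) + 1, size_gap=size_gap)
            dye = dyes[0]
            grp.members.append((m.marker_id, dye))
            groups.append(grp)
            intervals[(len(groups) - 1, dye)] = [(lo, hi)]
            m.dye, m.multiplex_group = dye, grp.group_id
    return groups


def write_panel_tsv(markers: list[MarkerDef], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tchrom\tpos\tsize_I\tsize_D\tdye\tgroup\n")
        for m in markers:
            size_i, size_d = m.allele_sizes if m.allele_sizes else ("", "")
            fh.write(
                f"{m.marker_id}\t{m.chrom}\t{m.position}\t{size_i}\t{size_d}\t"
                f"{m.dye or ''}\t{m.multiplex_group if m.multiplex_group is not None else ''}\n"
            )


def write_panel_bed(markers: list[MarkerDef], path: str) -> None:
    """Marker loci as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for m in markers:
            fh.write(f"{m.chrom}\t{m.position - 1}\t{m.position - 1 + max(m.indel_length, 1)}\t{m.marker_id}\n")
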