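"""Co-dominant genotype tables: data model, CSV/TSV I/O, validation,
biallelic recoding, and interoperability exports (PLINK PED/MAP, STRUCTURE,
GenAlEx-style CSV).

A genotype call is stored as a sorted tuple of allele labels (integer
fragment sizes in bp), or ``None`` for a missing call. A single observed
allele on a diploid is expanded to a homozygote — capillary chromatograms
report one peak for homozygotes. Polyploids keep their observed (<=2-allele)
set and are flagged ``dosage_unknown``; they take part in identity matching
but are excluded from diversity, Hardy-Weinberg and Fst computations.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import pandas as pd

MISSING_TOKENS = {"-", "", ".", "na", "nan", "n/a"}
METADATA_COLUMNS = [
    "accession_id",
    "name",
    "species",
    "ploidy",
    "parent1",
    "parent2",
    "lineage_group",
]

Call = tuple[int, ...] | None


@dataclass
class AccessionRecord:
    accession_id: str
    name: str = ""
    species: str = ""
    ploidy: int = 2
    parent1: str | None = None
    parent2: str | None = None
    lineage_group: str | None = None

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise ValueError(f"{self.accession_id}: ploidy must be >= 2")

    @property
    def dosage_unknown(self) -> bool:
        return self.ploidy > 2


def canonical_call(alleles, ploidy: int = 2) -> Call:
    """Sorted allele multiset; a single allele expands to a diploid homozygote."""
    if alleles is None:
        return None
    alleles = tuple(sorted(int(a) for a in alleles))
    if not alleles:
        return None
    if len(alleles) == 1 and ploidy == 2:
        alleles = (alleles[0], alleles[0])
    return alleles


def parse_cell(cell: str, ploidy: int = 2) -> Call:
    """Parse "a/b", "a" (homozygote) or "-" (missing)."""
    cell = cell.strip()
    if cell.lower() in MISSING_TOKENS:
        return None
    parts = [p for p in cell.replace("|", "/").split("/") if p.strip()]
    try:
        return canonical_call([int(p) for p in parts], ploidy)
    except ValueError as exc:
        raise ValueError(f"non-numeric allele in cell {cell!r}") from exc


def format_call(call: Call) -> str:
    if call is None:
        return "-"
    return "/".join(str(a) for a in call)


class GenotypeTable:
    """Accessions x markers matrix of unordered co-dominant allele multisets."""

    def __init__(self, markers: list[str], accessions: list[AccessionRecord], calls):
        if len(set(markers)) != len(markers):
            raise ValueError("marker ids must be unique")
        ids = [a.accession_id for a in accessions]
        if len(set(ids)) != len(ids):
            raise ValueError("accession ids must be unique")
        self.markers = list(markers)
        self.accessions = list(accessions)
        # calls: list (per accession) of list (per marker) of Call
        self.calls: list[list[Call]] = [list(row) for row in calls]
        for row in self.calls:
            if len(row) != len(markers):
                raise ValueError("ragged call matrix")
        if len(self.calls) != len(accessions):
            raise ValueError("call matrix row count != accession count")
        self._acc_index = {a.accession_id: i for i, a in enumerate(self.accessions)}
        self._marker_index = {m: j for j, m in enumerate(self.markers)}

    # -- basic access ------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def accession(self, accession_id: str) -> AccessionRecord:
        return self.accessions[self._acc_index[accession_id]]

    def __contains__(self, accession_id: str) -> bool:
        return accession_id in self._acc_index

    def call(self, accession_id: str, marker_id: str) -> Call:
        return self.calls[self._acc_index[accession_id]][self._marker_index[marker_id]]

    def row(self, accession_id: str) -> dict[str, Call]:
        r = self.calls[self._acc_index[accession_id]]
        return dict(zip(self.markers, r))

    def subset(self, accession_ids=None, marker_ids=None) -> "GenotypeTable":
        acc_ids = list(accession_ids) if accession_ids is not None else [
            a.accession_id for a in self.accessions
        ]
        mks = list(marker_ids) if marker_ids is not None else list(self.markers)
        mj = [self._marker_index[m] for m in mks]
        accs = [self.accession(a) for a in acc_ids]
        calls = [[self.calls[self._acc_index[a]][j] for j in mj] for a in acc_ids]
        return GenotypeTable(mks, accs, calls)

    def observed_alleles(self, marker_id: str, accession_ids=None) -> list[int]:
        """Sorted distinct alleles observed at a marker."""
        j = self._marker_index[marker_id]
        rows = (
            range(len(self.accessions))
            if accession_ids is None
            else [self._acc_index[a] for a in accession_ids]
        )
        seen: set[int] = set()
        for i in rows:
            c = self.calls[i][j]
            if c is not None:
                seen.update(c)
        return sorted(seen)

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "accession_id": [a.accession_id for a in self.accessions],
                "name": [a.name for a in self.accessions],
                "species": [a.species for a in self.accessions],
                "ploidy": [a.ploidy for a in self.accessions],
                "parent1": [a.parent1 or "" for a in self.accessions],
                "parent2": [a.parent2 or "" for a in self.accessions],
                "lineage_group": [a.lineage_group or "" for a in self.accessions],
            }
        )
        geno = pd.DataFrame(
            [[format_call(c) for c in row] for row in self.calls], columns=self.markers
        )
        return pd.concat([meta, geno], axis=1)


def write_genotype_table(table: GenotypeTable, path: str, sep: str = ",") -> None:
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def read_genotype_table(path: str) -> GenotypeTable:
    """Read the documented CSV/TSV dialect (delimiter sniffed).

    Header: metadata columns (at minimum ``accession_id``; the rest of
    METADATA_COLUMNS optional) followed by one column per marker. Cells are
    "a/b", "a" (homozygote shorthand) or "-" (missing).
    """
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "accession_id" not in df.columns:
        raise ValueError("genotype table must have an 'accession_id' column")
    marker_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    accessions, calls = [], []
    for ridx, row in df.iterrows():
        ploidy = int(row["ploidy"]) if "ploidy" in df.columns and row["ploidy"] else 2
        accessions.append(
            AccessionRecord(
                accession_id=row["accession_id"],
                name=row.get("name", "") or "",
                species=row.get("species", "") or "",
                ploidy=ploidy,
                parent1=row.get("parent1") or None,
                parent2=row.get("parent2") or None,
                lineage_group=row.get("lineage_group") or None,
            )
        )
        parsed = []
        for m in marker_cols:
            try:
                parsed.append(parse_cell(row[m], ploidy))
            except ValueError as exc:
                raise ValueError(f"row {ridx + 2}, marker {m}: {exc}") from exc
        calls.append(parsed)
    return GenotypeTable(marker_cols, accessions, calls)


@dataclass(frozen=True)
class Finding:
    kind: str  # excess_alleles | unexpected_allele | monomorphic | missing_rate
    accession_id: str | None
    marker_id: str | None
    detail: str


def validate_table(
    table: GenotypeTable,
    expected_alleles: dict[str, set[int]] | None = None,
    missing_rate_warn: float = 0.1,
) -> list[Finding]:
    """Consistency findings: diploid calls with >2 distinct alleles, alleles
    outside a marker's declared size set, monomorphic markers, and per-marker
    missing rates above ``missing_rate_warn``. Findings, never exceptions.
    """
    findings: list[Finding] = []
    for i, acc in enumerate(table.accessions):
        for j, m in enumerate(table.markers):
            c = table.calls[i][j]
            if c is None:
                continue
            if acc.ploidy == 2 and len(set(c)) > 2:
                findings.append(
                    Finding("excess_alleles", acc.accession_id, m, f"call {format_call(c)}")
                )
            if expected_alleles and m in expected_alleles:
                bad = set(c) - expected_alleles[m]
                if bad:
                    findings.append(
                        Finding(
                            "unexpected_allele",
                            acc.accession_id,
                            m,
                            f"allele(s) {sorted(bad)} not in declared set",
                        )
                    )
    n = table.n_accessions
    for j, m in enumerate(table.markers):
        col = [table.calls[i][j] for i in range(n)]
        present = [c for c in col if c is not None]
        distinct = {a for c in present for a in c}
        if len(distinct) <= 1:
            findings.append(Finding("monomorphic", None, m, f"{len(distinct)} allele(s) observed"))
        miss = 1.0 - len(present) / n if n else 0.0
        if miss > missing_rate_warn:
            findings.append(Finding("missing_rate", None, m, f"missing rate {miss:.3f}"))
    return findings


@dataclass
class BiallelicCoding:
    """Outcome of insertion/deletion recoding over a chosen accession set."""

    table: GenotypeTable  # calls coded with 1 = D (smaller fragment), 2 = I (larger)
    biallelic_markers: list[str]
    excluded_multiallelic: list[str]
    monomorphic: list[str]
    allele_map: dict[str, dict[int, int]]  # marker -> {size: code}

    def decode(self) -> GenotypeTable:
        """Restore fragment sizes on the biallelic markers (inverse map)."""
        inv = {m: {v: k for k, v in mp.items()} for m, mp in self.allele_map.items()}
        calls = []
        for row in self.table.calls:
            calls.append(
                [
                    None if c is None else tuple(sorted(inv[m][a] for a in c))
                    for m, c in zip(self.table.markers, row)
                ]
            )
        return GenotypeTable(self.table.markers, self.table.accessions, calls)


CODE_D, CODE_I = 1, 2


def recode_biallelic(table: GenotypeTable, accession_ids=None) -> BiallelicCoding:
    """Recode markers to insertion/deletion codes over the given accessions.

    A marker is biallelic iff exactly two distinct alleles are observed among
    the chosen accessions; the larger fragment (insertion allele) codes as
    ``CODE_I``, the smaller as ``CODE_D``. Markers with >= 3 observed alleles
    are excluded and listed; single-allele markers are retained but flagged
    monomorphic.
    """
    acc_ids = (
        list(accession_ids)
        if accession_ids is not None
        else [a.accession_id for a in table.accessions]
    )
    sub = table.subset(accession_ids=acc_ids)
    biallelic, excluded, mono = [], [], []
    allele_map: dict[str, dict[int, int]] = {}
    for m in sub.markers:
        obs = sub.observed_alleles(m)
        if len(obs) == 2:
            biallelic.append(m)
            allele_map[m] = {obs[0]: CODE_D, obs[1]: CODE_I}
        elif len(obs) > 2:
            excluded.append(m)
        else:
            mono.append(m)
            if obs:
                allele_map[m] = {obs[0]: CODE_D}
    keep = [m for m in sub.markers if m in allele_map]
    coded_rows = []
    for acc in sub.accessions:
        row = []
        for m in keep:
            c = sub.call(acc.accession_id, m)
            row.append(None if c is None else tuple(sorted(allele_map[m][a] for a in c)))
        coded_rows.append(row)
    coded = GenotypeTable(keep, sub.accessions, coded_rows)
    return BiallelicCoding(coded, biallelic, excluded, mono, allele_map)


# -- interoperability exports ---------------------------------------------


def export_plink(coding: BiallelicCoding, prefix: str, diploids_only: bool = True) -> None:
    """PED/MAP pair for the biallelic markers (PLINK 1.x text dialect).

    Allele codes: 1 = deletion allele, 2 = insertion allele; missing "0 0".
    Multiallelic markers were already excluded by the coding step.
    """
    markers = coding.biallelic_markers
    tb = coding.table
    with open(prefix + ".map", "w") as fh:
        for m in markers:
            fh.write(f"0\t{m}\t0\t0\n")
    with open(prefix + ".ped", "w") as fh:
        for acc in tb.accessions:
            if diploids_only and acc.ploidy != 2:
                continue
            fields = [acc.accession_id, acc.accession_id, "0", "0", "0", "-9"]
            for m in markers:
                c = tb.call(acc.accession_id, m)
                if c is None or len(c) != 2:
                    fields += ["0", "0"]
                else:
                    fields += [str(c[0]), str(c[1])]
            fh.write(" ".join(fields) + "\n")


def export_structure(coding: BiallelicCoding, path: str, diploids_only: bool = True) -> None:
    """STRUCTURE two-rows-per-individual format; missing coded -9."""
    markers = coding.biallelic_markers
    tb = coding.table
    pops = sorted({a.species for a in tb.accessions})
    pop_code = {p: i + 1 for i, p in enumerate(pops)}
    with open(path, "w") as fh:
        fh.write("\t".join(markers) + "\n")
        for acc in tb.accessions:
            if diploids_only and acc.ploidy != 2:
                continue
            for k in range(2):
                alleles = []
                for m in markers:
                    c = tb.call(acc.accession_id, m)
                    alleles.append("-9" if c is None or len(c) != 2 else str(c[k]))
                fh.write(
                    "\t".join([acc.accession_id, str(pop_code[acc.species])] + alleles) + "\n"
                )


def read_structure(path: str) -> dict[str, list[tuple[int, int] | None]]:
    """Minimal STRUCTURE reader (round-trip checking aid)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n_markers = len(lines[0].split("\t"))
    out: dict[str, list] = {}
    body = lines[1:]
    for r1, r2 in zip(body[0::2], body[1::2]):
        f1, f2 = r1.split("\t"), r2.split("\t")
        acc = f1[0]
        calls = []
        for a, b in zip(f1[2 : 2 + n_markers], f2[2 : 2 + n_markers]):
            if a == "-9" or b == "-9":
                calls.append(None)
            else:
                calls.append(tuple(sorted((int(a), int(b)))))
        out[acc] = calls
    return out


def export_genalex(table: GenotypeTable, path: str, diploids_only: bool = True) -> None:
    """GenAlEx-style co-dominant CSV: three header rows, then one row per
    sample with two allele columns per locus (missing 0)."""
    accs = [a for a in table.accessions if not (diploids_only and a.ploidy != 2)]
    pops = sorted({a.species for a in accs})
    counts = [sum(1 for a in accs if a.species == p) for p in pops]
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow([len(table.markers), len(accs), len(pops)] + counts)
    w.writerow(["gik export", "", ""] + pops)
    header = ["Sample", "Pop"]
    for m in table.markers:
        header += [m, ""]
    w.writerow(header)
    for acc in accs:
        row = [acc.accession_id, acc.species or "pop1"]
        for m in table.markers:
            c = table.call(acc.accession_id, m)
            if c is None or len(c) != 2:
                row += [0, 0]
            else:
                row += [c[0], c[1]]
        w.writerow(row)
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())
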