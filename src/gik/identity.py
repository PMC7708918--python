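"""Identity signatures and germplasm curation reports.

A cultivar's identity signature is the canonical combination of its
genotypes across the marker panel: one "marker=alleleA|alleleB" field per
marker, sorted by marker id, joined by ";", with missing calls encoded "?".
Equal genotype multisets therefore give byte-equal strings (and equal SHA-256
digests) regardless of row, column or within-call allele order.

On top of the signatures this module groups duplicate accessions, classifies
names into synonyms / homonyms / replicates, measures how many clonal bud
sports a panel can tell apart within each lineage, and renders a text
payload suitable for QR encoding.
"""

from __future__ import annotations

import hashlib
import re
import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field

from .genotypes import Call, GenotypeTable

PAYLOAD_PREFIX = "GIK1"
#: conservative capacity of a version-40 binary QR symbol
QR_MAX_BYTES = 2953


@dataclass(frozen=True)
class IdentitySignature:
    canonical_string: str
    digest: str

    @staticmethod
    def from_calls(calls: dict[str, Call]) -> "IdentitySignature":
        if not calls:
            raise ValueError("empty marker panel")
        parts = []
        for m in sorted(calls):
            c = calls[m]
            parts.append(f"{m}=?" if c is None else f"{m}=" + "|".join(str(a) for a in sorted(c)))
        s = ";".join(parts)
        return IdentitySignature(s, hashlib.sha256(s.encode()).hexdigest())


@dataclass
class IdentityGroup:
    signature: IdentitySignature
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GroupingSummary:
    n_accessions: int
    n_distinct: int
    n_singleton: int
    n_shared_groups: int


@dataclass
class GroupingResult:
    groups: list[IdentityGroup]
    summary: GroupingSummary
    #: pairs of accessions whose signatures coincide once missing cells are
    #: ignored — reported, never merged (wildcard matching is non-transitive)
    possible_duplicates: list[tuple[str, str]] = field(default_factory=list)

    def group_of(self, accession_id: str) -> IdentityGroup:
        for g in self.groups:
            if accession_id in g.members:
                return g
        raise KeyError(accession_id)


def signature_of(table: GenotypeTable, accession_id: str, markers=None) -> IdentitySignature:
    row = table.row(accession_id)
    if markers is not None:
        row = {m: row[m] for m in markers}
    return IdentitySignature.from_calls(row)


def _wildcard_compatible(rowa: list[Call], rowb: list[Call]) -> bool:
    # rows come from distinct exact groups, so agreement at every co-typed
    # marker means only missingness separates them
    return all(a is None or b is None or a == b for a, b in zip(rowa, rowb))


def group_by_signature(table: GenotypeTable, match_mode: str = "exact") -> GroupingResult:
    """Partition accessions by exact canonical signature.

    ``wildcard_report`` mode additionally lists accession pairs from distinct
    groups that would match if missing cells were ignored; those pairs are a
    report only and are never merged.
    """
    if match_mode not in ("exact", "wildcard_report"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    by_sig: dict[str, list[str]] = defaultdict(list)
    sigs: dict[str, IdentitySignature] = {}
    for acc in table.accessions:
        sig = signature_of(table, acc.accession_id)
        by_sig[sig.canonical_string].append(acc.accession_id)
        sigs.setdefault(sig.canonical_string, sig)
    groups = [
        IdentityGroup(sigs[s], members) for s, members in sorted(by_sig.items())
    ]
    n_single = sum(1 for g in groups if g.size == 1)
    summary = GroupingSummary(
        n_accessions=table.n_accessions,
        n_distinct=len(groups),
        n_singleton=n_single,
        n_shared_groups=len(groups) - n_single,
    )
    possible: list[tuple[str, str]] = []
    if match_mode == "wildcard_report":
        reps = [(g.members[0], table.calls[table._acc_index[g.members[0]]]) for g in groups]
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                if _wildcard_compatible(reps[i][1], reps[j][1]):
                    possible.append((reps[i][0], reps[j][0]))
    return GroupingResult(groups, summary, possible)


_PUNCT = re.compile(r"[\s\W_]+", flags=re.UNICODE)


def normalize_name(name: str, alias_map: dict[str, str] | None = None) -> str:
    """Conservative normalization: NFKC case-fold, strip punctuation and
    whitespace; user-supplied alias map applied last (curator knowledge)."""
    s = unicodedata.normalize("NFKC", name).casefold()
    s = _PUNCT.sub("", s)
    if alias_map:
        s = alias_map.get(s, s)
    return s


@dataclass
class NameClassification:
    labels: dict[str, str]  # accession_id -> unique|synonym|homonym|replicate|unclassified
    synonym_clusters: list[list[str]]
    homonym_clusters: list[list[str]]
    replicate_clusters: list[list[str]]

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)


def classify_names(
    grouping: GroupingResult,
    table: GenotypeTable,
    alias_map: dict[str, str] | None = None,
) -> NameClassification:
    """Label accessions by the name/signature cross-classification.

    replicate: same signature and same normalized name as another accession;
    synonym: same signature, different normalized name; homonym: same
    normalized name, different signature. Precedence replicate > synonym >
    homonym; everything else is ``unique``.
    """
    norm = {
        a.accession_id: normalize_name(a.name or a.accession_id, alias_map)
        for a in table.accessions
    }
    labels = {a.accession_id: "unique" for a in table.accessions}
    synonym_clusters, replicate_clusters = [], []
    for g in grouping.groups:
        if g.size < 2:
            continue
        names = defaultdict(list)
        for m in g.members:
            names[norm[m]].append(m)
        reps = [c for c in names.values() if len(c) > 1]
        for cluster in reps:
            replicate_clusters.append(sorted(cluster))
            for m in cluster:
                labels[m] = "replicate"
        if len(names) > 1:
            syn = sorted(m for m in g.members if labels[m] != "replicate")
            if syn:
                synonym_clusters.append(syn)
                for m in syn:
                    labels[m] = "synonym"
    by_name = defaultdict(list)
    for acc_id, n in norm.items():
        by_name[n].append(acc_id)
    sig_of = {m: g.signature.digest for g in grouping.groups for m in g.members}
    homonym_clusters = []
    for n, members in by_name.items():
        if len(members) < 2:
            continue
        if len({sig_of[m] for m in members}) > 1:
            cluster = sorted(m for m in members if labels[m] == "unique")
            if cluster:
                homonym_clusters.append(cluster)
            for m in members:
                if labels[m] == "unique":
                    labels[m] = "homonym"
    return NameClassification(labels, synonym_clusters, homonym_clusters, replicate_clusters)


@dataclass
class LineageReport:
    lineage: str
    n: int
    n_distinguishable: int
    percent: float  # rounded to 1 decimal
    subgroups: list[list[str]]  # shared-signature subgroups (size >= 2)


def sport_discrimination(table: GenotypeTable) -> list[LineageReport]:
    """Per clonal lineage: how many bud sports carry a signature unique
    within the lineage, and the shared-signature subgroups of the rest."""
    lineages: dict[str, list[str]] = defaultdict(list)
    for acc in table.accessions:
        if acc.lineage_group:
            lineages[acc.lineage_group].append(acc.accession_id)
    reports = []
    for lineage in sorted(lineages):
        members = lineages[lineage]
        if not members:
            continue
        by_sig: dict[str, list[str]] = defaultdict(list)
        for m in members:
            by_sig[signature_of(table, m).canonical_string].append(m)
        uniq = [v[0] for v in by_sig.values() if len(v) == 1]
        shared = sorted(
            (sorted(v) for v in by_sig.values() if len(v) > 1), key=lambda g: (-len(g), g)
        )
        n = len(members)
        reports.append(
            LineageReport(
                lineage=lineage,
                n=n,
                n_distinguishable=len(uniq),
                percent=round(100.0 * len(uniq) / n, 1),
                subgroups=shared,
            )
        )
    return reports


@dataclass
class WildtypeComparison:
    polymorphic: list[str]
    uncomparable: list[str]  # missing on one side only


def compare_to_wildtype(table: GenotypeTable, sport_id: str, wildtype_id: str) -> WildtypeComparison:
    """Markers whose canonical calls differ between a sport and its wildtype.

    A marker missing in exactly one of the two accessions is uncomparable,
    not polymorphic.
    """
    for acc in (sport_id, wildtype_id):
        if acc not in table:
            raise KeyError(f"unknown accession {acc!r}")
    poly, unc = [], []
    rs, rw = table.row(sport_id), table.row(wildtype_id)
    for m in table.markers:
        a, b = rs[m], rw[m]
        if a is None and b is None:
            continue
        if a is None or b is None:
            unc.append(m)
        elif a != b:
            poly.append(m)
    return WildtypeComparison(poly, unc)


def qr_payload(
    accession_id: str,
    signature: IdentitySignature,
    panel_version: str = "v1",
    digest_only: bool = False,
    max_bytes: int = QR_MAX_BYTES,
) -> str:
    """Deterministic UTF-8 text payload for a QR symbol.

    Full mode carries the whole canonical genotype string (decodable by
    :func:`parse_qr_payload`); digest-only mode carries the SHA-256 digest
    when the full payload would exceed QR capacity.
    """
    if digest_only:
        payload = "|".join([PAYLOAD_PREFIX + "D", accession_id, panel_version, signature.digest])
    else:
        payload = "|".join(
            [PAYLOAD_PREFIX, accession_id, panel_version, signature.canonical_string]
        )
    if len(payload.encode()) > max_bytes:
        raise ValueError(
            f"payload is {len(payload.encode())} bytes, above QR capacity "
            f"{max_bytes}; use digest_only=True"
        )
    return payload


def parse_qr_payload(payload: str) -> dict:
    head, accession_id, panel_version, body = payload.split("|", 3)
    if head == PAYLOAD_PREFIX + "D":
        return {
            "accession_id": accession_id,
            "panel_version": panel_version,
            "digest": body,
        }
    if head != PAYLOAD_PREFIX:
        raise ValueError(f"not a recognised payload: {head!r}")
    calls: dict[str, Call] = {}
    for part in body.split(";"):
        m, v = part.split("=", 1)
        calls[m] = None if v == "?" else tuple(int(x) for x in v.split("|"))
    return {
        "accession_id": accession_id,
        "panel_version": panel_version,
        "calls": calls,
    }
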