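"""Orthologous-group (OG) catalog: the criteria definitions behind FFASC.

An OG groups homologous proteins assumed to affect free-fatty-acid (FFA)
production equivalently.  Each OG carries a category that selects its
quantification rule:

* ``nOG`` — presence hurts FFA production (criterion value ``-hitN``),
* ``pOG`` — presence helps (``hitN``, with a ``-1`` penalty when absent),
* ``rOG`` — required for FA synthesis (``hitN``).

The catalog also records, per member protein, the set of Pfam domain
accessions a homology hit must cover to count (the domain-completeness
filter).  The order of OGs in the catalog file is authoritative: every
matrix built downstream uses it as its column order.

File format: TSV with columns ``og_id, category, action_label,
member_protein_id, domain_accessions`` (semicolon-separated accessions,
column optional when empty), one row per member protein, ``#`` comments,
UTF-8.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from .errors import (
    CatalogFormatError,
    DuplicateMembershipError,
    DuplicateOGError,
    UnknownActionError,
    UnknownCategoryError,
)

CATEGORIES = ("nOG", "pOG", "rOG")
ACTION_LABELS = (
    "present",
    "overexpression",
    "insert",
    "knockout",
    "knockdown",
    "underexpression",
)

_HEADER = "og_id\tcategory\taction_label\tmember_protein_id\tdomain_accessions"


@dataclass(frozen=True)
class DomainRequirement:
    """Pfam domain families a hit to this member protein must cover."""

    protein_id: str
    domain_accessions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if any(not a for a in self.domain_accessions):
            raise CatalogFormatError(
                f"empty domain accession for protein {self.protein_id!r}"
            )


@dataclass(frozen=True)
class OGDefinition:
    og_id: str
    category: str
    action_label: str
    member_protein_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise UnknownCategoryError(
                f"OG {self.og_id}: unknown category {self.category!r}"
            )
        if self.action_label not in ACTION_LABELS:
            raise UnknownActionError(
                f"OG {self.og_id}: unknown action label {self.action_label!r}"
            )
        if not self.member_protein_ids:
            raise CatalogFormatError(f"OG {self.og_id}: no member proteins")

    @property
    def feature_name(self) -> str:
        """Criterion feature name, ``<action>_<og_id>_<representative>``."""
        return f"{self.action_label}_{self.og_id}_{self.member_protein_ids[0]}"


@dataclass
class OGCatalog:
    """Ordered collection of OG definitions plus per-member domain rules."""

    ogs: list[OGDefinition]
    domain_requirements: dict[str, DomainRequirement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_og: set[str] = set()
        index: dict[str, str] = {}
        for og in self.ogs:
            if og.og_id in seen_og:
                raise DuplicateOGError(f"duplicate OG id {og.og_id!r}")
            seen_og.add(og.og_id)
            for pid in og.member_protein_ids:
                if pid in index:
                    raise DuplicateMembershipError(
                        f"protein {pid!r} listed in both {index[pid]!r} "
                        f"and {og.og_id!r}"
                    )
                index[pid] = og.og_id
        self._member_index = index

    @property
    def og_ids(self) -> list[str]:
        return [og.og_id for og in self.ogs]

    @property
    def member_index(self) -> Mapping[str, str]:
        """Map member protein id -> owning og_id (exact inverse of members)."""
        return dict(self._member_index)

    @property
    def categories(self) -> dict[str, str]:
        return {og.og_id: og.category for og in self.ogs}

    def __len__(self) -> int:
        return len(self.ogs)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._member_index

    def og_of(self, protein_id: str) -> str:
        return self._member_index[protein_id]

    def required_domains(self, protein_id: str) -> frozenset[str]:
        req = self.domain_requirements.get(protein_id)
        return req.domain_accessions if req is not None else frozenset()

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for og in self.ogs:
            counts[og.category] += 1
        return counts

    def n_members(self) -> int:
        return sum(len(og.member_protein_ids) for og in self.ogs)


@dataclass
class CatalogReport:
    """Read-only validation summary produced by :func:`validate_catalog`."""

    n_ogs: int
    n_members: int
    category_counts: dict[str, int]
    members_without_domains: list[str]
    warnings: list[str]


def _parse_row(fields: list[str], lineno: int) -> tuple[str, str, str, str, frozenset[str]]:
    if len(fields) not in (4, 5):
        raise CatalogFormatError(
            f"line {lineno}: expected 4 or 5 tab-separated fields, "
            f"got {len(fields)}"
        )
    og_id, category, action, member = (f.strip() for f in fields[:4])
    if not og_id or not member:
        raise CatalogFormatError(f"line {lineno}: empty og_id or member id")
    domains: frozenset[str] = frozenset()
    if len(fields) == 5 and fields[4].strip():
        domains = frozenset(d.strip() for d in fields[4].split(";") if d.strip())
    return og_id, category, action, member, domains


def load_catalog(source: str | Path | TextIO) -> OGCatalog:
    """Load an :class:`OGCatalog` from a TSV file or text stream.

    OG order is the order of first appearance; member order within an OG is
    row order.  Raises the named validation errors on duplicate OG ids,
    duplicate membership, and unknown categories or action labels.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return load_catalog(fh)

    order: list[str] = []
    meta: dict[str, tuple[str, str]] = {}
    members: dict[str, list[str]] = {}
    requirements: dict[str, DomainRequirement] = {}

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip() == "og_id":  # header row
            continue
        og_id, category, action, member, domains = _parse_row(fields, lineno)
        if og_id not in meta:
            order.append(og_id)
            meta[og_id] = (category, action)
            members[og_id] = []
        elif meta[og_id] != (category, action):
            raise DuplicateOGError(
                f"line {lineno}: OG {og_id!r} redefined with conflicting "
                f"category/action"
            )
        members[og_id].append(member)
        requirements[member] = DomainRequirement(member, domains)

    ogs = [
        OGDefinition(og_id, meta[og_id][0], meta[og_id][1], tuple(members[og_id]))
        for og_id in order
    ]
    return OGCatalog(ogs, requirements)


def save_catalog(catalog: OGCatalog, target: str | Path | TextIO) -> None:
    """Write the canonical TSV form (sorted domain accessions, no comments).

    ``save(load(x))`` is byte-identical for canonically formatted inputs.
    """
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            save_catalog(catalog, fh)
        return
    target.write(_HEADER + "\n")
    for og in catalog.ogs:
        for pid in og.member_protein_ids:
            domains = ";".join(sorted(catalog.required_domains(pid)))
            row = [og.og_id, og.category, og.action_label, pid]
            if domains:
                row.append(domains)
            target.write("\t".join(row) + "\n")


def dumps_catalog(catalog: OGCatalog) -> str:
    buf = io.StringIO()
    save_catalog(catalog, buf)
    return buf.getvalue()


def validate_catalog(catalog: OGCatalog) -> CatalogReport:
    """Summarise a catalog without mutating it.

    Reports category counts, members lacking domain requirements (their hits
    bypass the domain-completeness filter), and structural warnings.
    """
    warnings: list[str] = []
    if not catalog.ogs:
        warnings.append("empty catalog")
    no_domains = [
        pid
        for og in catalog.ogs
        for pid in og.member_protein_ids
        if not catalog.required_domains(pid)
    ]
    if no_domains:
        warnings.append(
            f"{len(no_domains)} member protein(s) have no domain requirements; "
            "their hits bypass the domain-completeness filter"
        )
    return CatalogReport(
        n_ogs=len(catalog),
        n_members=catalog.n_members(),
        category_counts=catalog.category_counts(),
        members_without_domains=no_domains,
        warnings=warnings,
    )


def default_catalog() -> OGCatalog:
    """The shipped catalog: 49 OGs (13 nOG, 24 pOG, 12 rOG), 64 members."""
    ref = resources.files("ffasc.data").joinpath("default_catalog.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_catalog(fh)


def iter_feature_names(catalog: OGCatalog) -> Iterable[str]:
    for og in catalog.ogs:
        yield og.feature_name
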