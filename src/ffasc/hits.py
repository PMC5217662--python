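"""Homology-hit detection: parse search outputs, filter, count per OG.

The screening pipeline maps the catalog's member proteins against each
candidate proteome with BLASTp and screens the resulting homologs with the
member's Pfam domain models.  This module consumes those outputs — BLAST
tabular (``-outfmt 6``) and HMMER ``--domtblout`` files — and produces the
species × OG hit-count matrix ``C`` (entries ``hitN``) after two filters:

1. e-value filter: keep hits with e-value ≤ 1e-4 (inclusive);
2. domain-completeness filter: keep a hit only if the target protein carries
   *all* Pfam domains required for the query member protein.  Members with
   no recorded domain requirement bypass this filter.

External tool invocations that produce these files (not run here)::

    blastp -query og_members.faa -db species_proteome -outfmt 6 -evalue 10
    hmmsearch --cut_tc --domtblout species.domtbl pfam_subset.hmm proteome.faa
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence, TextIO

import numpy as np
import pandas as pd

from .catalog import OGCatalog
from .errors import ParseError, UnknownQueryProteinError, UnknownSpeciesError

DEFAULT_EVALUE_THRESHOLD = 1e-4

#: How a hitN is counted: distinct (query member, target protein) pairs
#: (multiple HSPs for one pair collapse to one) or distinct target proteins
#: per OG regardless of which member matched them.
CountUnit = Literal["query_target_pairs", "distinct_targets"]


@dataclass(frozen=True)
class HomologyHit:
    query_protein_id: str
    target_protein_id: str
    target_species_id: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value!r}")


@dataclass(frozen=True)
class DomainAnnotation:
    target_protein_id: str
    domain_accession: str
    meets_trusted_cutoff: bool = True

    def __post_init__(self) -> None:
        if not self.domain_accession:
            raise ValueError("empty domain accession")


def _open_lines(source: str | Path | TextIO) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def parse_blast_tabular(
    source: str | Path | TextIO, species_id: str
) -> list[HomologyHit]:
    """Parse BLAST ``-outfmt 6`` lines into :class:`HomologyHit` records.

    Field 1 is the query (catalog member protein), field 2 the target
    protein in the screened proteome, field 11 the e-value; the other nine
    standard columns are ignored.  Line order is preserved.
    """
    hits: list[HomologyHit] = []
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(
                f"expected ≥12 tab-separated fields, got {len(fields)}", lineno
            )
        try:
            evalue = float(fields[10])
        except ValueError:
            raise ParseError(f"non-numeric e-value {fields[10]!r}", lineno) from None
        if evalue < 0:
            raise ParseError(f"negative e-value {fields[10]!r}", lineno)
        hits.append(HomologyHit(fields[0], fields[1], species_id, evalue))
    return hits


def strip_accession_version(accession: str) -> str:
    """``PF00108.21`` -> ``PF00108`` (trailing ``.NN`` version removed)."""
    head, sep, tail = accession.rpartition(".")
    if sep and tail.isdigit():
        return head
    return accession


def parse_domtblout(source: str | Path | TextIO) -> list[DomainAnnotation]:
    """Parse a HMMER ``--domtblout`` table into domain annotations.

    Layout follows ``hmmsearch`` with sequence targets: column 1 is the
    target protein id and column 5 the query profile accession (the Pfam
    family, version suffix stripped).  ``#`` comment lines are skipped.
    Rows are assumed to have passed the trusted-cutoff threshold at search
    time (``--cut_tc``); the flag is recorded as True.
    """
    annotations: list[DomainAnnotation] = []
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 22:
            raise ParseError(
                f"expected ≥22 whitespace-separated fields, got {len(fields)}",
                lineno,
            )
        accession = strip_accession_version(fields[4])
        if accession == "-":
            # hmmsearch emits "-" when the profile has no accession; fall
            # back to the profile name.
            accession = fields[3]
        annotations.append(DomainAnnotation(fields[0], accession, True))
    return annotations


def filter_by_evalue(
    hits: Sequence[HomologyHit], threshold: float = DEFAULT_EVALUE_THRESHOLD
) -> list[HomologyHit]:
    """Retain hits with ``e_value <= threshold`` (inclusive), stable order."""
    if threshold <= 0:
        raise ValueError("e-value threshold must be positive")
    return [h for h in hits if h.e_value <= threshold]


def select_domain_complete_hits(
    hits: Sequence[HomologyHit],
    annotations: Sequence[DomainAnnotation],
    catalog: OGCatalog,
) -> list[HomologyHit]:
    """Keep hits whose target carries all domains required by the query.

    A target's domain set is the set of trusted-cutoff-passing accessions
    annotated for it; a hit survives iff that set is a superset of the
    query member's required set.  Queries with an empty required set keep
    all their hits (vacuous superset).
    """
    target_domains: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.meets_trusted_cutoff:
            target_domains.setdefault(ann.target_protein_id, set()).add(
                ann.domain_accession
            )
    kept: list[HomologyHit] = []
    for hit in hits:
        if hit.query_protein_id not in catalog:
            raise UnknownQueryProteinError(
                f"query protein {hit.query_protein_id!r} is not in the catalog"
            )
        required = catalog.required_domains(hit.query_protein_id)
        if required <= target_domains.get(hit.target_protein_id, set()):
            kept.append(hit)
    return kept


def build_hit_matrix(
    hits: Sequence[HomologyHit],
    catalog: OGCatalog,
    species_ids: Sequence[str],
    count_unit: CountUnit = "query_target_pairs",
) -> pd.DataFrame:
    """Aggregate filtered hits into the species × OG hit-count matrix C.

    Entry ``(i, j)`` is hitN: the number of distinct counting units among
    retained hits whose query belongs to OG ``j`` and whose target species
    is ``i``.  Species with no hits get all-zero rows.  Column order equals
    catalog order.
    """
    og_ids = catalog.og_ids
    species_index = {s: i for i, s in enumerate(species_ids)}
    og_index = {og: j for j, og in enumerate(og_ids)}
    units: set[tuple] = set()
    for hit in hits:
        if hit.query_protein_id not in catalog:
            raise UnknownQueryProteinError(
                f"query protein {hit.query_protein_id!r} is not in the catalog"
            )
        if hit.target_species_id not in species_index:
            raise UnknownSpeciesError(
                f"species {hit.target_species_id!r} not in declared species list"
            )
        og = catalog.og_of(hit.query_protein_id)
        if count_unit == "query_target_pairs":
            key = (hit.target_species_id, og, hit.query_protein_id,
                   hit.target_protein_id)
        else:
            key = (hit.target_species_id, og, hit.target_protein_id)
        units.add(key)
    values = np.zeros((len(species_ids), len(og_ids)), dtype=np.int64)
    for key in units:
        values[species_index[key[0]], og_index[key[1]]] += 1
    return pd.DataFrame(values, index=list(species_ids), columns=og_ids)


def count_hits(
    catalog: OGCatalog,
    blast_sources: dict[str, str | Path | TextIO],
    domtbl_sources: dict[str, str | Path | TextIO] | None = None,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    count_unit: CountUnit = "query_target_pairs",
) -> pd.DataFrame:
    """Full pipeline: parse → e-value filter → domain filter → count.

    ``blast_sources`` maps species id → BLAST outfmt-6 payload;
    ``domtbl_sources`` maps species id → domtblout payload (optional per
    species).  Returns the hit-count matrix with one row per species key.
    """
    all_hits: list[HomologyHit] = []
    for species_id, src in blast_sources.items():
        hits = parse_blast_tabular(src, species_id)
        hits = filter_by_evalue(hits, evalue_threshold)
        annotations: list[DomainAnnotation] = []
        if domtbl_sources and species_id in domtbl_sources:
            annotations = parse_domtblout(domtbl_sources[species_id])
        all_hits.extend(select_domain_complete_hits(hits, annotations, catalog))
    return build_hit_matrix(
        all_hits, catalog, list(blast_sources.keys()), count_unit
    )
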