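"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to the screen are proteome-scale BLAST and HMMER outputs that
cannot be bundled or regenerated quickly; this module fabricates small but
format-faithful stand-ins — catalogs, outfmt-6 / domtblout payloads with
planted hit counts and decoy hits, reference-pair criteria matrices for
the weight optimizer, and blob-plus-outgroup layouts for the cluster
validation — each carrying the ground truth needed to verify the code
that consumes it.

Planted hit counts are Poisson with per-category means (defaults
nOG 0.5, pOG 1.5, rOG 1.0), chosen to exercise both the pOG absence
penalty (hitN = 0) and multi-hit counting.  Decoys come in two flavours,
each defeating exactly one filter: e-value decoys (e-value > threshold,
domain-complete) and domain decoys (good e-value, one required domain
missing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import DomainRequirement, OGCatalog, OGDefinition

DEFAULT_CATEGORY_FRACTIONS = {"nOG": 13 / 49, "pOG": 24 / 49, "rOG": 12 / 49}
DEFAULT_HIT_MEANS = {"nOG": 0.5, "pOG": 1.5, "rOG": 1.0}
_ACTION_FOR_CATEGORY = {"nOG": "knockout", "pOG": "overexpression", "rOG": "present"}
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DecoyRecord:
    """One injected hit that the pipeline must filter out."""

    species_id: str
    query_protein_id: str
    target_protein_id: str
    filtered_by: str  # "evalue" or "domain"


@dataclass
class FixtureBundle:
    catalog: OGCatalog
    ground_truth: pd.DataFrame  # species × OG planted hit counts
    blast_files: dict[str, str]  # species id -> outfmt-6 text
    domtbl_files: dict[str, str]  # species id -> domtblout text
    fasta_files: dict[str, str] = field(default_factory=dict)
    decoy_log: list[DecoyRecord] = field(default_factory=list)


def _allocate_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder rounding of n·fraction per category."""
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("category fractions must sum to 1")
    raw = {c: n * f for c, f in fractions.items()}
    counts = {c: math.floor(v) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(fractions, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def generate_catalog(
    n_ogs: int = 49,
    category_fractions: dict[str, float] | None = None,
    members_per_og: int | tuple[int, int] = (1, 2),
    domains_per_member: int | tuple[int, int] = (0, 3),
    seed: int = 0,
) -> OGCatalog:
    """Random catalog with the requested shape; deterministic per seed.

    Category counts follow largest-remainder rounding of the fractions
    (the defaults reproduce the 13/24/12 split of the shipped catalog).
    Member and domain counts are drawn uniformly from the given ranges;
    members with zero domains exercise the filter-bypass path.
    """
    if n_ogs < 1:
        raise ValueError("need at least one OG")
    fractions = category_fractions or DEFAULT_CATEGORY_FRACTIONS
    counts = _allocate_counts(n_ogs, fractions)
    rng = np.random.default_rng(seed)

    def _draw(spec: int | tuple[int, int]) -> int:
        if isinstance(spec, int):
            return spec
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))

    ogs: list[OGDefinition] = []
    requirements: dict[str, DomainRequirement] = {}
    i = 0
    for category in ("nOG", "pOG", "rOG"):
        for _ in range(counts.get(category, 0)):
            og_id = f"K9{i:04d}"
            n_members = max(1, _draw(members_per_og))
            members = tuple(f"{og_id}_m{t}" for t in range(n_members))
            for pid in members:
                n_dom = _draw(domains_per_member)
                domains = frozenset(
                    f"PF{int(rng.integers(10000, 99999)):05d}" for _ in range(n_dom)
                )
                requirements[pid] = DomainRequirement(pid, domains)
            ogs.append(
                OGDefinition(og_id, category, _ACTION_FOR_CATEGORY[category], members)
            )
            i += 1
    return OGCatalog(ogs, requirements)


def _blast_line(query: str, target: str, evalue: float) -> str:
    return (
        f"{query}\t{target}\t92.31\t120\t8\t0\t1\t120\t1\t120\t"
        f"{evalue:.3g}\t215.0"
    )


def _domtbl_line(target: str, accession: str) -> str:
    name = accession.split(".")[0]
    return (
        f"{target:<20s} -            250 {name:<12s} {accession:<12s}  120 "
        "  1.2e-30  101.5   0.1   1   1   4.1e-33   1.5e-30  100.8   0.1 "
        "    1   120     5   124     3   126 0.97 synthetic fixture domain"
    )


def _random_peptide(rng: np.random.Generator, length: int = 50) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def generate_fixture_bundle(
    catalog: OGCatalog,
    n_species: int = 6,
    hit_rate_params: dict[str, float] | None = None,
    decoy_params: dict[str, int] | None = None,
    seed: int = 0,
    evalue_threshold: float = 1e-4,
    with_fasta: bool = False,
) -> FixtureBundle:
    """Plant a hit matrix and emit the raw search payloads that encode it.

    Replaying parse → e-value filter → domain filter → count on the
    payloads reconstructs ``ground_truth`` exactly; every decoy listed in
    ``decoy_log`` is absent from the reconstruction and traceable to the
    single filter that removes it.
    """
    rng = np.random.default_rng(seed)
    means = {**DEFAULT_HIT_MEANS, **(hit_rate_params or {})}
    decoys = {"evalue": 0, "domain": 0, **(decoy_params or {})}
    species_ids = [f"SP{i:03d}" for i in range(n_species)]
    og_ids = catalog.og_ids
    truth = np.zeros((n_species, len(og_ids)), dtype=np.int64)

    blast: dict[str, list[str]] = {s: [] for s in species_ids}
    domtbl: dict[str, list[str]] = {s: [] for s in species_ids}
    fasta: dict[str, list[str]] = {s: [] for s in species_ids}
    target_counter = 0

    for si, sp in enumerate(species_ids):
        for oj, og in enumerate(catalog.ogs):
            mean = means[og.category]
            for member in og.member_protein_ids:
                n_hits = int(rng.poisson(mean))
                for _ in range(n_hits):
                    target = f"{sp}_t{target_counter}"
                    target_counter += 1
                    evalue = float(10.0 ** rng.uniform(-40, math.log10(evalue_threshold)))
                    blast[sp].append(_blast_line(member, target, evalue))
                    for acc in sorted(catalog.required_domains(member)):
                        domtbl[sp].append(_domtbl_line(target, f"{acc}.7"))
                    if with_fasta:
                        fasta[sp].append(f">{target}\n{_random_peptide(rng)}")
                truth[si, oj] += n_hits

    # decoys: injected hits that exactly one filter must remove
    members = [pid for og in catalog.ogs for pid in og.member_protein_ids]
    with_domains = [m for m in members if catalog.required_domains(m)]
    decoy_log: list[DecoyRecord] = []
    for _ in range(decoys.get("evalue", 0)):
        sp = species_ids[int(rng.integers(n_species))]
        member = members[int(rng.integers(len(members)))]
        target = f"{sp}_decoyE{target_counter}"
        target_counter += 1
        evalue = float(10.0 ** rng.uniform(math.log10(evalue_threshold) + 0.5, 1.0))
        blast[sp].append(_blast_line(member, target, evalue))
        # domain-complete on purpose: only the e-value filter may remove it
        for acc in sorted(catalog.required_domains(member)):
            domtbl[sp].append(_domtbl_line(target, f"{acc}.7"))
        decoy_log.append(DecoyRecord(sp, member, target, "evalue"))
    if decoys.get("domain", 0) and not with_domains:
        raise ValueError(
            "domain decoys require at least one member with domain requirements"
        )
    for _ in range(decoys.get("domain", 0)):
        sp = species_ids[int(rng.integers(n_species))]
        member = with_domains[int(rng.integers(len(with_domains)))]
        target = f"{sp}_decoyD{target_counter}"
        target_counter += 1
        evalue = float(10.0 ** rng.uniform(-40, math.log10(evalue_threshold)))
        blast[sp].append(_blast_line(member, target, evalue))
        required = sorted(catalog.required_domains(member))
        for acc in required[:-1]:  # withhold one required domain
            domtbl[sp].append(_domtbl_line(target, f"{acc}.7"))
        decoy_log.append(DecoyRecord(sp, member, target, "domain"))

    ground_truth = pd.DataFrame(truth, index=species_ids, columns=og_ids)
    return FixtureBundle(
        catalog=catalog,
        ground_truth=ground_truth,
        blast_files={s: "\n".join(lines) + ("\n" if lines else "") for s, lines in blast.items()},
        domtbl_files={
            s: "# synthetic domtblout\n" + "\n".join(lines) + ("\n" if lines else "")
            for s, lines in domtbl.items()
        },
        fasta_files={s: "\n".join(lines) + ("\n" if lines else "") for s, lines in fasta.items()}
        if with_fasta
        else {},
        decoy_log=decoy_log,
    )


def generate_reference_pair(
    m: int | Sequence[str] = 49,
    n_species: int = 20,
    planted_delta: Sequence[float] | None = None,
    seed: int = 0,
    noise_scale: float = 0.05,
) -> tuple[pd.DataFrame, str, str]:
    """Criteria matrix with a designated positive/negative reference pair.

    The pair's rows straddle a common midpoint so that ``pos − neg`` equals
    ``planted_delta`` exactly; the remaining species scatter around the
    midpoint with standard deviation ``noise_scale``.  The default delta
    concentrates the whole effect on one coordinate, the layout the weight
    optimizer must resolve by pushing that coordinate's weight to its
    upper bound.
    """
    og_ids = [f"OG{j:03d}" for j in range(m)] if isinstance(m, int) else list(m)
    mdim = len(og_ids)
    rng = np.random.default_rng(seed)
    if planted_delta is None:
        planted_delta = np.zeros(mdim)
        planted_delta[rng.integers(mdim)] = 8.0
    delta = np.asarray(planted_delta, dtype=float)
    if delta.shape[0] != mdim:
        raise ValueError("planted_delta length must match number of OGs")
    mid = rng.normal(0.0, 1.0, mdim)
    rows = [mid + delta / 2.0, mid - delta / 2.0]
    ids = ["SP_POS", "SP_NEG"]
    for i in range(n_species - 2):
        rows.append(mid + rng.normal(0.0, noise_scale, mdim))
        ids.append(f"SP{i:03d}")
    return pd.DataFrame(np.vstack(rows), index=ids, columns=og_ids), "SP_POS", "SP_NEG"


def generate_clustered_species(
    k: int = 5,
    cluster_sizes: Sequence[int] | int = 25,
    separation: float = 25.0,
    n_outliers: int = 3,
    seed: int = 0,
    m: int = 49,
    outlier_distance: float | None = None,
    outlier_spread: float = 2.5,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Gaussian blobs plus a distant outgroup, with planted labels.

    Emulates the screened layout: ``k`` in-group clusters (unit-variance
    blobs around centers ``separation`` apart in expectation) and a small
    outgroup placed beyond the in-group span — near enough to join the
    in-group partition at small k, far enough to claim its own cluster
    once every blob has one.  Returns (matrix, labels, outlier_ids);
    outliers carry label ``k + 1``.
    """
    if k < 2:
        raise ValueError("need at least 2 in-group clusters")
    if separation <= 0:
        raise ValueError("separation must be positive")
    sizes = [cluster_sizes] * k if isinstance(cluster_sizes, int) else list(cluster_sizes)
    if len(sizes) != k:
        raise ValueError("cluster_sizes length must equal k")
    rng = np.random.default_rng(seed)

    # centers on random directions with norm separation/sqrt(2), so the
    # expected center-center distance is ~separation
    dirs = rng.normal(size=(k, m))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = dirs * (separation / math.sqrt(2.0))

    rows, labels, ids = [], [], []
    for c, size in enumerate(sizes):
        block = centers[c] + rng.normal(0.0, 1.0, (size, m))
        rows.append(block)
        labels.extend([c + 1] * size)
        ids.extend(f"SP{c}_{i:02d}" for i in range(size))

    d_out = outlier_distance if outlier_distance is not None else 1.2 * separation
    out_dir = rng.normal(size=m)
    out_dir /= np.linalg.norm(out_dir)
    out_center = out_dir * d_out
    outliers = out_center + rng.normal(0.0, outlier_spread, (n_outliers, m))
    rows.append(outliers)
    labels.extend([k + 1] * n_outliers)
    outlier_ids = [f"OUT{i}" for i in range(n_outliers)]
    ids.extend(outlier_ids)

    matrix = pd.DataFrame(
        np.vstack(rows), index=ids, columns=[f"OG{j:03d}" for j in range(m)]
    )
    return matrix, np.asarray(labels), outlier_ids
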