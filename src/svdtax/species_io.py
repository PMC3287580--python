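"""Reading and writing species sequences, taxonomies, distance matrices and partitions.

A *species record* couples one concatenated amino-acid sequence (e.g. the 13
mitochondrial gene families of a vertebrate, joined end to end) with an
ordered 14-rank Linnaean lineage, Superregnum first, Species last.  All
downstream stages — trigram featurization, SVD reduction, clustering and the
Linnaean quality statistics — operate on these records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: The 20 standard amino acids, lexicographic.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical Linnaean rank names, index 0 = rank 1 (Superregnum) … index 13 = rank 14 (Species).
RANK_NAMES = (
    "Superregnum", "Regnum", "Subregnum", "Cladus1", "Cladus2", "Phylum",
    "Subphylum", "Infraphylum", "Classis", "Subclassis", "Ordo", "Familia",
    "Genus", "Species",
)

N_RANKS = 14

_STANDARD = frozenset(AMINO_ACIDS)


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass
class SpeciesRecord:
    """One species: id, short display mnemonic, cleaned protein sequence, lineage.

    ``lineage`` is either ``None`` (not yet joined with a taxonomy table) or a
    tuple of exactly 14 non-empty taxon names in canonical rank order.
    """

    species_id: str
    sequence: str
    mnemonic: str = ""
    lineage: tuple[str, ...] | None = None
    cleaning_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lineage is not None:
            self.lineage = tuple(self.lineage)
            if len(self.lineage) != N_RANKS or any(not t for t in self.lineage):
                raise ValidationError(
                    f"lineage of {self.species_id!r} must have {N_RANKS} non-empty ranks"
                )


@dataclass
class Dataset:
    """An ordered collection of species records plus control groups.

    The positive control is a species set a valid clustering configuration
    must isolate integrally in one cluster (the role the class Aves plays in
    the mitochondrial corpus); the optional secondary control refines
    tie-breaking between otherwise equivalent configurations.
    """

    records: list[SpeciesRecord]
    positive_control: frozenset[str] = frozenset()
    secondary_control: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValidationError("a dataset needs at least 2 species")
        ids = [r.species_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate species ids in dataset")
        self.positive_control = frozenset(self.positive_control)
        known = set(ids)
        if not self.positive_control <= known:
            raise ValidationError("positive control contains unknown species ids")
        if self.secondary_control is not None:
            self.secondary_control = frozenset(self.secondary_control)
            if not self.secondary_control <= known:
                raise ValidationError("secondary control contains unknown species ids")

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self.records]

    def subset(self, keep: Iterable[str]) -> "Dataset":
        """Restrict to ``keep`` (original order preserved); controls intersected."""
        keep = set(keep)
        recs = [r for r in self.records if r.species_id in keep]
        sec = None
        if self.secondary_control is not None:
            sec = self.secondary_control & keep
            sec = sec if sec else None
        return Dataset(recs, self.positive_control & keep, sec)


def clean_sequence(raw: str) -> tuple[str, dict[str, int]]:
    """Uppercase ``raw`` and strip everything outside the 20-letter alphabet.

    Ambiguity codes (B, J, O, U, X, Z), stop marks and gap characters are
    removed rather than rejected, keeping the 20^3 trigram space
    well-defined; the removals are tallied so a run report can surface them.
    """
    counts: dict[str, int] = {}
    kept = []
    for ch in raw.upper():
        if ch in _STANDARD:
            kept.append(ch)
        elif ch.isspace():
            continue
        else:
            counts[ch] = counts.get(ch, 0) + 1
    return "".join(kept), counts


def _default_mnemonic(species_id: str, lineage: Sequence[str] | None) -> str:
    if lineage is not None:
        genus, species = lineage[12], lineage[13]
        epithet = species.split()[-1]
        return (genus[:1] + epithet[:3]).capitalize()
    stem = re.sub(r"[^A-Za-z0-9]", "", species_id)
    return (stem[:4] or "Sp").capitalize()


def assign_mnemonics(records: Sequence[SpeciesRecord]) -> None:
    """Fill missing 4-letter mnemonics, de-duplicating with numeric suffixes."""
    seen: set[str] = {r.mnemonic for r in records if r.mnemonic}
    for rec in records:
        if rec.mnemonic:
            continue
        base = _default_mnemonic(rec.species_id, rec.lineage)
        name, i = base, 1
        while name in seen:
            i += 1
            name = f"{base}{i}"
        seen.add(name)
        rec.mnemonic = name


def read_species_fasta(
    fasta_path: str | Path,
    grouping: Mapping[str, str] | None = None,
) -> list[SpeciesRecord]:
    """Read a protein multi-FASTA into one record per species.

    Without ``grouping`` each FASTA record is its own species (id = first
    whitespace-delimited token of the header).  With ``grouping`` (gene
    record id → species id) all records of a species are concatenated in
    file order — the construction used for per-species proteome records
    built from several gene families.

    Non-standard residues are removed and tallied per species; a species
    left with an empty sequence is a validation error.
    """
    fasta_path = Path(fasta_path)
    order: list[str] = []
    parts: dict[str, list[str]] = {}
    n_seen = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_seen += 1
        rid = rec.id
        if grouping is not None:
            if rid not in grouping:
                raise ValidationError(f"FASTA record {rid!r} missing from grouping map")
            sid = grouping[rid]
        else:
            sid = rid
        if sid not in parts:
            parts[sid] = []
            order.append(sid)
        parts[sid].append(str(rec.seq))
    if n_seen == 0:
        raise FormatError(f"{fasta_path}: no FASTA records found")

    records = []
    for sid in order:
        seq, counts = clean_sequence("".join(parts[sid]))
        if not seq:
            raise ValidationError(f"species {sid!r} has no standard residues after cleaning")
        records.append(SpeciesRecord(sid, seq, cleaning_counts=counts))
    return records


def read_taxonomy(tsv_path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a 15-column TSV (species_id + 14 ranks, Superregnum first).

    Returns species_id → lineage tuple.  Rows of the wrong arity raise a
    format error naming the line; duplicate ids are a validation error.
    Distinct ids may share a lineage (ids, not lineages, key the table).
    """
    tsv_path = Path(tsv_path)
    taxonomy: dict[str, tuple[str, ...]] = {}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 1 + N_RANKS:
                raise FormatError(
                    f"{tsv_path}:{lineno}: expected {1 + N_RANKS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            sid, *ranks = [f.strip() for f in fields]
            if not sid or any(not r for r in ranks):
                raise FormatError(f"{tsv_path}:{lineno}: empty field")
            if sid in taxonomy:
                raise ValidationError(f"duplicate species id {sid!r} in taxonomy")
            taxonomy[sid] = tuple(ranks)
    if not taxonomy:
        raise FormatError(f"{tsv_path}: empty taxonomy table")
    return taxonomy


def attach_lineages(
    records: Sequence[SpeciesRecord], taxonomy: Mapping[str, Sequence[str]]
) -> list[SpeciesRecord]:
    """Join records with a taxonomy table; every record must be present."""
    out = []
    for rec in records:
        if rec.species_id not in taxonomy:
            raise ValidationError(f"no lineage for species {rec.species_id!r}")
        out.append(replace(rec, lineage=tuple(taxonomy[rec.species_id])))
    assign_mnemonics(out)
    return out


def write_taxonomy(taxonomy: Mapping[str, Sequence[str]], tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        for sid, lineage in taxonomy.items():
            fh.write("\t".join([sid, *lineage]) + "\n")


def write_species_fasta(records: Sequence[SpeciesRecord], fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.species_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices

def _phylip_labels(labels: Sequence[str]) -> list[str]:
    out, seen = [], set()
    for lab in labels:
        trunc = lab[:10]
        name, i = trunc, 1
        while name in seen:
            i += 1
            suffix = str(i)
            name = trunc[: 10 - len(suffix)] + suffix
        seen.add(name)
        out.append(name)
    return out


def write_phylip_distances(matrix, labels: Sequence[str]) -> str:
    """Render a symmetric distance matrix in PHYLIP square format.

    Labels longer than 10 characters are truncated (uniquified); values are
    printed with 6 decimals, the layout NEIGHBOR consumes.
    """
    import numpy as np

    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n) or len(labels) != n:
        raise ValidationError("matrix must be square with one label per row")
    if np.max(np.abs(m - m.T)) > 1e-9:
        raise ValidationError("distance matrix is asymmetric beyond 1e-9")
    labs = _phylip_labels(labels)
    lines = [str(n)]
    for i in range(n):
        row = " ".join(f"{m[i, j]:.6f}" for j in range(n))
        lines.append(f"{labs[i]:<10}{row}")
    return "\n".join(lines) + "\n"


def read_phylip_distances(text: str):
    """Parse PHYLIP square format back to (matrix, labels)."""
    import numpy as np

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty PHYLIP input")
    n = int(lines[0].split()[0])
    if len(lines) != n + 1:
        raise FormatError(f"expected {n} taxon rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        labels.append(ln[:10].strip())
        rows.append([float(x) for x in ln[10:].split()])
    m = np.asarray(rows, dtype=float)
    if m.shape != (n, n):
        raise FormatError("ragged PHYLIP matrix")
    return m, labels


# ---------------------------------------------------------------------------
# Partition TSV

def write_partition(partition, id_to_mnemonic: Mapping[str, str] | None = None) -> str:
    """Partition → TSV (cluster_index, species_id, mnemonic).

    Clusters are numbered 1.. in descending size, ties broken by smallest
    member id; members listed sorted within a cluster.
    """
    clusters = [sorted(c) for c in partition.clusters]
    if not clusters:
        raise ValidationError("empty partition")
    seen: set[str] = set()
    for c in clusters:
        if not c:
            raise ValidationError("empty cluster in partition")
        if seen & set(c):
            raise ValidationError("overlapping clusters in partition")
        seen |= set(c)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    lines = ["cluster_index\tspecies_id\tmnemonic"]
    for idx, members in enumerate(clusters, start=1):
        for sid in members:
            mn = id_to_mnemonic.get(sid, "") if id_to_mnemonic else ""
            lines.append(f"{idx}\t{sid}\t{mn}")
    return "\n".join(lines) + "\n"


def read_partition(text: str) -> list[frozenset[str]]:
    """Parse a partition TSV back to its list of clusters."""
    clusters: dict[int, set[str]] = {}
    lines = text.splitlines()
    for ln in lines[1:]:
        if not ln.strip():
            continue
        idx_s, sid, *_ = ln.split("\t")
        clusters.setdefault(int(idx_s), set()).add(sid)
    return [frozenset(clusters[i]) for i in sorted(clusters)]
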