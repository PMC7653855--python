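"""Mutation catalogs and binary genotype matrices from resequenced ALE isolates.

An adaptive-laboratory-evolution (ALE) experiment yields, per replicate
culture and sampling time-point, a single sequenced clone.  Variant calls on
those clones are summarised in two artifacts:

* a *mutation catalog*: one row per distinct variant (gene, genomic
  coordinate, nucleotide change, protein effect, frequency among all
  sequenced isolates, first time-point of observation);
* a *genotype matrix*: isolates (culture x time-point) as rows, catalogued
  mutations as columns, binary presence/absence calls.

This module parses, validates and serialises both, and computes the
trajectory statistics used to summarise an evolution experiment: per-mutation
frequency, first occurrence, the set of persistent target genes, and the
exact mutations shared by all replicates at a time-point.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MutationRecord",
    "Isolate",
    "GenotypeMatrix",
    "CatalogError",
    "parse_change",
    "parse_mutation_table",
    "write_mutation_table",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "mutation_frequency",
    "first_occurrence",
    "persistent_target_genes",
    "shared_exact_mutations",
]


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog/matrix content."""


_TIMEPOINT_RE = re.compile(r"^T\d+$")
# Nucleotide-change notations, tolerant of unicode minus/arrow:
#   SNV        "T -> G"  /  "T → G"
#   deletion   "-7:ATCGCTA"  or bare "-15" (sequence unknown)
#   insertion  "+1:T"
_SNV_RE = re.compile(r"^([ACGT])\s*(?:→|->)\s*([ACGT])$")
_DEL_RE = re.compile(r"^[−–-]\s*(\d+)(?:\s*:\s*([ACGTN]+))?$")
_INS_RE = re.compile(r"^\+\s*(\d+)\s*:\s*([ACGTN]+)$")


def parse_change(change: str) -> tuple[str, str, int]:
    """Classify a nucleotide-change string.

    Returns ``(change_kind, ref_or_seq, length)`` where *change_kind* is one
    of ``snv``, ``deletion`` or ``insertion``.  For an SNV ``ref_or_seq`` is
    the normalised "X -> Y" string and length is 1; for indels it is the
    removed/added sequence (possibly empty when only a length was printed).
    """
    text = change.strip()
    if m := _SNV_RE.match(text):
        return "snv", f"{m.group(1)} -> {m.group(2)}", 1
    if m := _INS_RE.match(text):
        length, seq = int(m.group(1)), m.group(2)
        if length != len(seq):
            raise CatalogError(
                f"insertion length {length} does not match sequence {seq!r}"
            )
        return "insertion", seq, length
    if m := _DEL_RE.match(text):
        length, seq = int(m.group(1)), m.group(2) or ""
        if seq and length != len(seq):
            raise CatalogError(
                f"deletion length {length} does not match sequence {seq!r}"
            )
        return "deletion", seq, length
    raise CatalogError(f"unrecognised nucleotide-change notation: {change!r}")


@dataclass(frozen=True)
class MutationRecord:
    """One catalogued variant from the resequencing of ALE isolates."""

    mutation_id: str
    gene: str
    coordinate: int
    change_kind: str
    ref_or_seq: str
    length: int
    effect: str = ""
    reported_frequency_pct: int | None = None
    first_timepoint: str | None = None

    def __post_init__(self) -> None:
        if self.coordinate < 1:
            raise CatalogError(f"{self.mutation_id}: coordinate must be >= 1")
        if self.length < 1:
            raise CatalogError(f"{self.mutation_id}: length must be >= 1")
        if self.change_kind not in ("snv", "deletion", "insertion"):
            raise CatalogError(
                f"{self.mutation_id}: unknown change_kind {self.change_kind!r}"
            )
        if self.change_kind == "snv" and self.length != 1:
            raise CatalogError(f"{self.mutation_id}: SNV length must be 1")
        if (
            self.change_kind in ("deletion", "insertion")
            and self.ref_or_seq
            and len(self.ref_or_seq) != self.length
        ):
            raise CatalogError(
                f"{self.mutation_id}: length {self.length} inconsistent with "
                f"sequence {self.ref_or_seq!r}"
            )
        if self.first_timepoint is not None and not _TIMEPOINT_RE.match(
            self.first_timepoint
        ):
            raise CatalogError(
                f"{self.mutation_id}: bad time-point label {self.first_timepoint!r}"
            )

    @property
    def change(self) -> str:
        """Nucleotide change in catalog notation."""
        if self.change_kind == "snv":
            return self.ref_or_seq
        sign = "-" if self.change_kind == "deletion" else "+"
        if self.ref_or_seq:
            return f"{sign}{self.length}:{self.ref_or_seq}"
        return f"{sign}{self.length}"


_TABLE_COLUMNS = (
    "gene",
    "mutation_id",
    "coordinate",
    "change",
    "effect",
    "frequency_pct",
    "first_timepoint",
)


def parse_mutation_table(path) -> list[MutationRecord]:
    """Read a tab-separated mutation catalog.

    Expected header columns: gene, mutation_id, coordinate, change, effect,
    frequency_pct, first_timepoint.  Coordinates may contain thousands
    separators; frequency and time-point may be empty.
    """
    records: list[MutationRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise CatalogError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                kind, seq, length = parse_change(row["change"])
            except CatalogError as exc:
                raise CatalogError(f"{path} row {lineno}: {exc}") from exc
            coord = int(str(row["coordinate"]).replace(",", "").replace(" ", ""))
            freq = row.get("frequency_pct") or None
            tp = row.get("first_timepoint") or None
            rec = MutationRecord(
                mutation_id=row["mutation_id"].strip(),
                gene=row["gene"].strip(),
                coordinate=coord,
                change_kind=kind,
                ref_or_seq=seq,
                length=length,
                effect=(row.get("effect") or "").strip(),
                reported_frequency_pct=int(freq) if freq is not None else None,
                first_timepoint=tp.strip() if tp else None,
            )
            if rec.mutation_id in seen:
                raise CatalogError(
                    f"{path} row {lineno}: duplicate mutation_id {rec.mutation_id!r}"
                )
            seen.add(rec.mutation_id)
            records.append(rec)
    return records


def write_mutation_table(records: Iterable[MutationRecord], path) -> None:
    """Serialise a mutation catalog to the tab-separated interchange format."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(_TABLE_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.gene,
                    rec.mutation_id,
                    rec.coordinate,
                    rec.change,
                    rec.effect,
                    "" if rec.reported_frequency_pct is None else rec.reported_frequency_pct,
                    rec.first_timepoint or "",
                ]
            )


@dataclass(frozen=True)
class Isolate:
    """A sequenced clone: replicate culture, sampling time-point, generation."""

    culture: str
    timepoint: str
    generation: float


@dataclass
class GenotypeMatrix:
    """Binary presence/absence calls, isolates x mutations.

    ``provenance`` mirrors ``calls`` with per-cell flags: ``"s"`` for calls
    stated explicitly in the source report, ``"i"`` for calls reconstructed
    (inferred) from aggregate statistics.
    """

    isolates: list[Isolate]
    mutations: list[str]
    calls: list[list[int]]
    provenance: list[list[str]] | None = None

    def __post_init__(self) -> None:
        n, m = len(self.isolates), len(self.mutations)
        if len(self.calls) != n:
            raise CatalogError("calls row count does not match isolates")
        for i, row in enumerate(self.calls):
            if len(row) != m:
                raise CatalogError(f"row {i}: call count does not match mutations")
            for j, v in enumerate(row):
                if v not in (0, 1):
                    raise CatalogError(
                        f"non-binary call {v!r} at isolate "
                        f"{self.isolates[i].culture}-{self.isolates[i].timepoint}, "
                        f"mutation {self.mutations[j]}"
                    )
        if len(set(self.mutations)) != m:
            raise CatalogError("duplicate mutation column")
        if self.provenance is not None:
            if len(self.provenance) != n or any(
                len(r) != m for r in self.provenance
            ):
                raise CatalogError("provenance shape does not match calls")
        # generations must be strictly increasing within a culture
        per_culture: dict[str, list[float]] = {}
        for iso in self.isolates:
            per_culture.setdefault(iso.culture, []).append(iso.generation)
        for culture, gens in per_culture.items():
            if any(b <= a for a, b in zip(gens, gens[1:])):
                raise CatalogError(
                    f"culture {culture}: generations not strictly increasing"
                )

    # -- convenience ----------------------------------------------------

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)

    def column(self, mutation_id: str) -> list[int]:
        try:
            j = self.mutations.index(mutation_id)
        except ValueError:
            raise CatalogError(f"unknown mutation_id {mutation_id!r}") from None
        return [row[j] for row in self.calls]

    def genotype_of(self, culture: str, timepoint: str) -> frozenset[str]:
        """Mutation set carried by the isolate at (culture, timepoint)."""
        for iso, row in zip(self.isolates, self.calls):
            if iso.culture == culture and iso.timepoint == timepoint:
                return frozenset(
                    m for m, v in zip(self.mutations, row) if v
                )
        raise CatalogError(f"no isolate for culture {culture!r} at {timepoint!r}")

    def cultures(self) -> list[str]:
        seen: dict[str, None] = {}
        for iso in self.isolates:
            seen.setdefault(iso.culture)
        return list(seen)

    def validate_against(self, records: Sequence[MutationRecord]) -> None:
        """Check every matrix column resolves to a catalog record."""
        known = {r.mutation_id for r in records}
        unknown = [m for m in self.mutations if m not in known]
        if unknown:
            raise CatalogError(f"matrix columns not in catalog: {unknown}")


_MATRIX_META = ("culture", "timepoint", "generation")


def read_genotype_matrix(path, provenance_path=None) -> GenotypeMatrix:
    """Read a comma-separated genotype matrix.

    First columns are culture, timepoint, generation; every further column is
    a mutation_id with 0/1 entries.  An optional companion provenance file of
    identical shape carries per-cell ``s``/``i`` flags.
    """
    with open(path, newline="") as handle:
        rows = list(csv.reader(handle))
    if not rows:
        raise CatalogError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if tuple(header[:3]) != _MATRIX_META:
        raise CatalogError(
            f"{path}: first columns must be {_MATRIX_META}, got {header[:3]}"
        )
    mutations = header[3:]
    isolates: list[Isolate] = []
    calls: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) != len(header):
            raise CatalogError(f"{path} row {lineno}: wrong field count")
        culture, timepoint = row[0].strip(), row[1].strip()
        if not row[2].strip():
            raise CatalogError(f"{path} row {lineno}: missing generation")
        generation = float(row[2])
        values = []
        for mid, cell in zip(mutations, row[3:]):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise CatalogError(
                    f"{path} row {lineno}: non-binary value {cell!r} "
                    f"in column {mid}"
                )
            values.append(int(cell))
        isolates.append(Isolate(culture, timepoint, generation))
        calls.append(values)
    provenance = None
    if provenance_path is not None:
        with open(provenance_path, newline="") as handle:
            prows = list(csv.reader(handle))
        provenance = [
            [cell.strip() for cell in row[3:]] for row in prows[1:] if row
        ]
        for i, row in enumerate(provenance):
            for flag in row:
                if flag not in ("s", "i"):
                    raise CatalogError(
                        f"{provenance_path} row {i + 2}: bad flag {flag!r}"
                    )
    return GenotypeMatrix(isolates, mutations, calls, provenance)


def write_genotype_matrix(matrix: GenotypeMatrix, path, provenance_path=None) -> None:
    header = list(_MATRIX_META) + list(matrix.mutations)

    def _dump(target, grid):
        with open(target, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(header)
            for iso, row in zip(matrix.isolates, grid):
                gen = iso.generation
                gen_repr = int(gen) if float(gen).is_integer() else gen
                writer.writerow([iso.culture, iso.timepoint, gen_repr, *row])

    _dump(path, matrix.calls)
    if provenance_path is not None and matrix.provenance is not None:
        _dump(provenance_path, matrix.provenance)


# -- trajectory statistics ----------------------------------------------


def mutation_frequency(matrix: GenotypeMatrix, mutation_id: str) -> int:
    """Percent of sequenced isolates carrying the mutation.

    Rounded to the nearest integer, halves away from zero, matching how
    frequencies are reported in mutation catalogs (10/21 -> 48).
    """
    if matrix.n_isolates == 0:
        raise CatalogError("frequency undefined for an empty matrix")
    carriers = sum(matrix.column(mutation_id))
    return int(math.floor(100.0 * carriers / matrix.n_isolates + 0.5))


def first_occurrence(matrix: GenotypeMatrix, mutation_id: str) -> str | None:
    """Earliest time-point (by generation, across cultures) with a carrier."""
    column = matrix.column(mutation_id)
    best: tuple[float, str] | None = None
    for iso, call in zip(matrix.isolates, column):
        if call and (best is None or iso.generation < best[0]):
            best = (iso.generation, iso.timepoint)
    return best[1] if best else None


def _final_genotypes(matrix: GenotypeMatrix) -> dict[str, frozenset[str]]:
    """Genotype of each culture's isolate at the experiment-wide final time-point."""
    final_gen = max(iso.generation for iso in matrix.isolates)
    final_tp = {
        iso.culture: iso.timepoint
        for iso in matrix.isolates
        if iso.generation == final_gen
    }
    out: dict[str, frozenset[str]] = {}
    for culture in matrix.cultures():
        if culture not in final_tp:
            raise CatalogError(
                f"culture {culture!r} has no isolate at the final time-point"
            )
        out[culture] = matrix.genotype_of(culture, final_tp[culture])
    return out


def persistent_target_genes(
    matrix: GenotypeMatrix, records: Sequence[MutationRecord]
) -> set[str]:
    """Genes mutated in the final isolate of every culture.

    Allelic variants of a gene (or regulatory region) are grouped: a culture
    counts as hit if its final isolate carries *any* allele of the gene.
    """
    gene_of = {r.mutation_id: r.gene for r in records}
    matrix.validate_against(records)
    finals = _final_genotypes(matrix)
    per_culture_genes = [
        {gene_of[m] for m in genotype} for genotype in finals.values()
    ]
    if not per_culture_genes:
        return set()
    return set.intersection(*per_culture_genes)


def shared_exact_mutations(matrix: GenotypeMatrix, timepoint: str) -> set[str]:
    """Mutation ids carried by every culture's isolate at *timepoint*."""
    genotypes = [
        matrix.genotype_of(culture, timepoint) for culture in matrix.cultures()
    ]
    return set(frozenset.intersection(*genotypes)) if genotypes else set()
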