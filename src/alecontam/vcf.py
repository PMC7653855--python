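"""Minimal VCF ingestion: map variant-caller records onto MutationRecords.

Only CHROM/POS/REF/ALT of biallelic records are used.  Indels follow the
VCF left-anchoring convention: REF=CATCGCTA ALT=C at POS=100 is a 7-bp
deletion whose removed sequence starts at coordinate 101.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping

import pysam

from .catalog import MutationRecord

__all__ = ["read_vcf_minimal"]


def read_vcf_minimal(
    path,
    id_map: Mapping[int, str] | Callable[[str, int], str] | None = None,
) -> list[MutationRecord]:
    """Read biallelic SNVs and simple indels from a VCF v4.2 file.

    ``id_map`` labels records with gene names: either a mapping from POS to
    gene or a callable ``(chrom, pos) -> gene``.  Unlabelled records use the
    chromosome name.  Multiallelic records are skipped with a warning.
    """

    def gene_for(chrom: str, pos: int) -> str:
        if id_map is None:
            return chrom
        if callable(id_map):
            return id_map(chrom, pos)
        return id_map.get(pos, chrom)

    records: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                warnings.warn(
                    f"skipping multiallelic record at {rec.chrom}:{rec.pos}",
                    stacklevel=2,
                )
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            gene = gene_for(rec.chrom, rec.pos)
            if len(ref) == 1 and len(alt) == 1:
                records.append(
                    MutationRecord(
                        mutation_id=f"{gene}_{rec.pos}",
                        gene=gene,
                        coordinate=rec.pos,
                        change_kind="snv",
                        ref_or_seq=f"{ref} -> {alt}",
                        length=1,
                    )
                )
            elif len(ref) > len(alt) and ref.startswith(alt):
                removed = ref[len(alt) :]
                records.append(
                    MutationRecord(
                        mutation_id=f"{gene}_{rec.pos}",
                        gene=gene,
                        coordinate=rec.pos + len(alt),
                        change_kind="deletion",
                        ref_or_seq=removed,
                        length=len(removed),
                    )
                )
            elif len(alt) > len(ref) and alt.startswith(ref):
                added = alt[len(ref) :]
                records.append(
                    MutationRecord(
                        mutation_id=f"{gene}_{rec.pos}",
                        gene=gene,
                        coordinate=rec.pos,
                        change_kind="insertion",
                        ref_or_seq=added,
                        length=len(added),
                    )
                )
            else:
                warnings.warn(
                    f"skipping complex allele at {rec.chrom}:{rec.pos} "
                    f"({ref}>{alt})",
                    stacklevel=2,
                )
    return records
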