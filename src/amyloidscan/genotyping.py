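"""Variant calling from amplicon reads and misread-floor estimation.

Reads cover the invariant Gly/Ser linker followed by the POI at fixed
offsets.  Genotyping is strict: exact read length (the library is
substitution-only, so any length change is an artifact), no ambiguous
bases, standard-table translation, and at most one amino-acid difference
from the wild-type POI.  The apparent mutation rate of the invariant
linker estimates the sequencing noise floor: a variant must exceed that
floor in the unselected library to be scored downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .counts import DISCARD_REASONS, CountTable
from .reference import CANONICAL_AA, CODON_TO_AA, ReferenceConstruct, VariantId

_VALID_BASES = frozenset("ACGT")


def genotype_read(read: str, reference: ReferenceConstruct) -> VariantId | str:
    """Call a single read: a VariantId, or a discard reason string.

    Rules (in order): reads shorter than the linker+POI window are
    ``truncated`` and longer ones ``indel-length``; any non-ACGT base is
    ``ambiguous-base``; a stop codon in the POI is ``premature-stop``;
    zero amino-acid differences from the wild-type POI give the WT
    sentinel, exactly one gives that variant, more give
    ``multi-substitution``.
    """
    expected = reference.read_length
    if len(read) < expected:
        return "truncated"
    if len(read) > expected:
        return "indel-length"
    if not _VALID_BASES.issuperset(read):
        return "ambiguous-base"

    poi_nt = read[3 * reference.n_linker:]
    poi_ref = reference.poi_sequence
    diff: tuple[int, str] | None = None
    for i in range(reference.n_poi):
        aa = CODON_TO_AA[poi_nt[3 * i : 3 * i + 3]]
        if aa == "*":
            return "premature-stop"
        if aa != poi_ref[i]:
            if diff is not None:
                return "multi-substitution"
            diff = (i + 1, aa)
    if diff is None:
        return VariantId.wildtype()
    pos, aa = diff
    return VariantId(pos, poi_ref[pos - 1], aa)


def _iter_reads(path: str | Path):
    path = Path(path)
    fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta"} else "fastq"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq).upper()


def build_count_table(
    fastq_files: dict[tuple[float, int], str | Path],
    reference: ReferenceConstruct,
) -> CountTable:
    """Aggregate genotype calls over all reads of every condition.

    ``fastq_files`` maps (ampicillin concentration, replicate) to a
    FASTQ/FASTA path.  Identical reads are genotyped once (memoised), so
    deeply sequenced conditions dominated by a few molecules are fast.
    Conservation holds per condition: assigned counts plus discard tallies
    equal the reads processed.
    """
    cache: dict[str, VariantId | str] = {}
    counts: dict[tuple[VariantId, float, int], int] = {}
    discarded: dict[tuple[float, int], dict[str, int]] = {}
    for (conc, rep), path in sorted(fastq_files.items()):
        tally: dict[str, int] = {r: 0 for r in DISCARD_REASONS}
        for read in _iter_reads(path):
            res = cache.get(read)
            if res is None:
                res = genotype_read(read, reference)
                cache[read] = res
            if isinstance(res, VariantId):
                key = (res, float(conc), int(rep))
                counts[key] = counts.get(key, 0) + 1
            else:
                tally[res] += 1
        discarded[(float(conc), int(rep))] = {k: v for k, v in tally.items() if v}
    return CountTable.from_mapping(counts, discarded)


@dataclass(frozen=True)
class MisreadEstimate:
    """Sequencing noise floor estimated from the invariant linker.

    ``per_condition_mean_linker_count`` is, for each condition, the number
    of apparent amino-acid substitutions observed in the linker divided by
    the number of linker positions; ``threshold`` (the reporting floor) is
    the ceiling of the mean of those values.
    """

    per_condition_mean_linker_count: dict[tuple[float, int], float]
    threshold: int


def estimate_misread_threshold(
    fastq_files: dict[tuple[float, int], str | Path],
    reference: ReferenceConstruct,
) -> MisreadEstimate:
    """Count apparent linker substitutions per condition and set the floor.

    The linker is invariant by construct design, so every canonical
    non-reference amino acid observed there is a misread.  Stop codons and
    reads of the wrong length are not counted as apparent variants.
    """
    n_linker = reference.n_linker
    linker_len = 3 * n_linker
    expected = reference.read_length
    linker_ref = reference.linker_sequence
    cache: dict[str, int] = {}
    per_condition: dict[tuple[float, int], float] = {}
    any_reads = False
    for (conc, rep), path in sorted(fastq_files.items()):
        events = 0
        n_reads = 0
        for read in _iter_reads(path):
            if len(read) != expected:
                continue
            n_reads += 1
            linker_nt = read[:linker_len]
            hit = cache.get(linker_nt)
            if hit is None:
                hit = 0
                for i in range(n_linker):
                    aa = CODON_TO_AA.get(linker_nt[3 * i : 3 * i + 3])
                    if aa is not None and aa != linker_ref[i] and aa in CANONICAL_AA:
                        hit += 1
                cache[linker_nt] = hit
            events += hit
        any_reads = any_reads or n_reads > 0
        per_condition[(float(conc), int(rep))] = events / n_linker
    if not any_reads:
        warnings.warn("no reads supplied; misread threshold set to 0")
        return MisreadEstimate(per_condition, 0)
    mean = sum(per_condition.values()) / len(per_condition)
    return MisreadEstimate(per_condition, math.ceil(mean))
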