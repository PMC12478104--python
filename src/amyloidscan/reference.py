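"""Reference construct, variant identifiers, and site-saturation enumeration.

The assayed construct is a tripartite beta-lactamase fusion: the peptide of
interest (POI) is inserted between the two TEM-1 domains via an invariant
Gly/Ser linker.  Sequencing reads cover the linker plus the POI, so the
reference tracked here is that window only: the linker amino acids (and
codons) followed by the POI amino acids (and codons).

Positions are 1-based within the POI; position 1 of the wild-type Abeta42
peptide is Asp1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Wild-type human Abeta42 (Asp1 ... Ala42).
ABETA42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: 28-residue Gly/Ser linker placed between the TEM-1 N-domain and the POI.
GS_LINKER_28 = "GS" * 14

#: One preferred E. coli codon per amino acid, used for read synthesis.
PREFERRED_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


def _codon_to_aa() -> dict[str, str]:
    """Standard-table codon -> amino acid map, with '*' for stop codons."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


#: codon (upper-case DNA) -> one-letter amino acid, '*' = stop.
CODON_TO_AA = _codon_to_aa()


@dataclass(frozen=True, order=True)
class VariantId:
    """One single-amino-acid substitution on the POI, or the WT sentinel.

    The wild-type sentinel is ``VariantId.wildtype()`` (position 0, empty
    residues); every real substitution has a 1-based ``position``, the
    wild-type residue ``wt_aa`` and the introduced residue ``mut_aa``.
    """

    position: int
    wt_aa: str
    mut_aa: str

    @classmethod
    def wildtype(cls) -> "VariantId":
        return cls(0, "", "")

    @property
    def is_wildtype(self) -> bool:
        return self.position == 0

    @property
    def label(self) -> str:
        """Conventional mutation label, e.g. ``L17P``; ``WT`` for the sentinel."""
        if self.is_wildtype:
            return "WT"
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @classmethod
    def from_label(cls, label: str) -> "VariantId":
        label = label.strip()
        if label.upper() == "WT":
            return cls.wildtype()
        wt, mut = label[0], label[-1]
        pos = int(label[1:-1])
        if wt not in CANONICAL_AA or mut not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue in variant label {label!r}")
        return cls(pos, wt, mut)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class ReferenceConstruct:
    """Sequenced window of the tripartite fusion: invariant linker + POI.

    Parameters
    ----------
    poi_sequence :
        Amino-acid sequence of the peptide of interest (1-based positions).
    linker_sequence :
        Invariant Gly/Ser linker upstream of the POI; its apparent mutation
        rate calibrates the sequencing noise floor.
    codon_map :
        Codon per residue over linker + POI, used when synthesising reads.
        Defaults to one preferred E. coli codon per amino acid.
    """

    poi_sequence: str
    linker_sequence: str = GS_LINKER_28
    codon_map: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for aa in self.poi_sequence:
            if aa not in CANONICAL_AA:
                raise ValueError(f"non-canonical residue {aa!r} in POI sequence")
        if not self.poi_sequence:
            raise ValueError("POI sequence must be non-empty")
        if set(self.linker_sequence) - {"G", "S"}:
            raise ValueError("linker must contain only Gly/Ser")
        if not self.codon_map:
            codons = tuple(
                PREFERRED_CODON[aa] for aa in self.linker_sequence + self.poi_sequence
            )
            object.__setattr__(self, "codon_map", codons)
        elif len(self.codon_map) != len(self.linker_sequence) + len(self.poi_sequence):
            raise ValueError("codon_map must cover linker + POI")

    @classmethod
    def abeta42(cls) -> "ReferenceConstruct":
        """The canonical Abeta42 construct (42 residues, 28-residue G/S linker)."""
        ref = cls(ABETA42)
        # Identity checks on positions referenced throughout downstream analyses.
        assert len(ref.poi_sequence) == 42
        assert ref.poi_sequence[3] == "F" and ref.poi_sequence[16] == "L"
        assert ref.poi_sequence[22] == "D" and ref.poi_sequence[41] == "A"
        return ref

    # ------------------------------------------------------------------
    # geometry of the sequenced window
    @property
    def n_linker(self) -> int:
        return len(self.linker_sequence)

    @property
    def n_poi(self) -> int:
        return len(self.poi_sequence)

    @property
    def read_length(self) -> int:
        """Nucleotide length of a structurally intact read (linker + POI)."""
        return 3 * (self.n_linker + self.n_poi)

    @property
    def linker_codons(self) -> tuple[str, ...]:
        return self.codon_map[: self.n_linker]

    @property
    def poi_codons(self) -> tuple[str, ...]:
        return self.codon_map[self.n_linker:]

    @lru_cache(maxsize=None)
    def wildtype_read(self) -> str:
        """Error-free nucleotide read of the linker + WT POI."""
        return "".join(self.codon_map)

    def variant_read(self, variant: VariantId) -> str:
        """Error-free nucleotide read carrying ``variant`` in the POI."""
        if variant.is_wildtype:
            return self.wildtype_read()
        if not 1 <= variant.position <= self.n_poi:
            raise ValueError(f"position {variant.position} outside POI")
        if self.poi_sequence[variant.position - 1] != variant.wt_aa:
            raise ValueError(f"{variant.label}: reference residue mismatch")
        codons = list(self.poi_codons)
        codons[variant.position - 1] = PREFERRED_CODON[variant.mut_aa]
        return "".join(self.linker_codons) + "".join(codons)


def enumerate_site_saturation(reference: ReferenceConstruct) -> list[VariantId]:
    """All single substitutions of the POI plus the WT sentinel.

    Every position is substituted with each of the 19 non-wild-type canonical
    amino acids, giving ``19 * L + 1`` variants (799 for Abeta42).  The WT
    sentinel is first; substitutions follow in (position, residue) order.
    """
    variants = [VariantId.wildtype()]
    for pos, wt in enumerate(reference.poi_sequence, start=1):
        for mut in CANONICAL_AA:
            if mut != wt:
                variants.append(VariantId(pos, wt, mut))
    return variants
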