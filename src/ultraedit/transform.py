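"""Reduced-alphabet transformations and the 12 alignment combinations.

A-to-I editing is read by sequencers as an A(genome)→G(RNA) substitution.
Replacing every A by G in *both* the genome and the RNA ("reduced" or
three-letter alphabet) masks these mismatches, so a heavily edited molecule
aligns cleanly to its locus.  Because the sequenced strand of both the cDNA
and the reference is arbitrary, the masking must be attempted under four
DNA-strand/RNA-strand combinations; three control substitutions (A→C, G→C,
A→T) estimate the background of spurious mismatch clusters.  G→C and A→T are
complement-symmetric, so their minus-DNA combinations are redundant and only
the plus-DNA ones are enumerated — 4 + 4 + 2 + 2 = 12 combinations in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Transformation",
    "TransformationCombo",
    "TRANSFORMATIONS",
    "MISMATCH_TYPES",
    "CANONICAL_TYPES",
    "canonical_type",
    "reduce_alphabet",
    "reverse_complement",
    "enumerate_combos",
    "masked_equal",
    "combo_table",
]

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

#: the 12 ordered mismatch types, genomic base → read base, on the + genome
MISMATCH_TYPES: tuple[str, ...] = tuple(
    f"{x}-to-{y}" for x in "ACGT" for y in "ACGT" if x != y
)

#: the six canonical (strand-folded) type labels used in reports; each of the
#: other six raw types is the −-strand manifestation of one of these
CANONICAL_TYPES: tuple[str, ...] = (
    "A-to-G", "G-to-A", "A-to-C", "C-to-A", "G-to-C", "A-to-T",
)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; IUPAC codes map to their complements."""
    rc = seq.translate(_COMPLEMENT)[::-1]
    bad = set(seq) - set("ACGTNRYSWKMBDHVacgtnryswkmbdhv")
    if bad:
        raise ValueError(f"cannot complement characters: {sorted(bad)!r}")
    return rc


def _complement_base(b: str) -> str:
    return b.translate(_COMPLEMENT)


def canonical_type(raw_type: str) -> tuple[str, str]:
    """Fold a raw mismatch type (on the + genome) to (canonical label, strand).

    A T-to-C cluster on the + genome is A-to-G editing of the − strand, and
    similarly for the other five complement pairs.
    """
    if raw_type in CANONICAL_TYPES:
        return raw_type, "+"
    x, y = raw_type.split("-to-")
    comp = f"{_complement_base(x)}-to-{_complement_base(y)}"
    if comp not in CANONICAL_TYPES:
        raise ValueError(f"unknown mismatch type {raw_type!r}")
    return comp, "-"


@dataclass(frozen=True)
class Transformation:
    """A single-base alphabet reduction, e.g. A→G replaces every A by G."""

    source_base: str
    target_base: str

    def __post_init__(self) -> None:
        if self.source_base == self.target_base:
            raise ValueError("source and target base must differ")

    @property
    def name(self) -> str:
        return f"{self.source_base}>{self.target_base}"

    def complement(self) -> "Transformation":
        return Transformation(
            _complement_base(self.source_base), _complement_base(self.target_base)
        )

    def masked_types(self) -> frozenset[str]:
        """The two reciprocal mismatch types this reduction makes invisible."""
        x, y = self.source_base, self.target_base
        return frozenset({f"{x}-to-{y}", f"{y}-to-{x}"})


#: the four reductions of the screen, keyed by two-letter id
TRANSFORMATIONS: dict[str, Transformation] = {
    "AG": Transformation("A", "G"),
    "AC": Transformation("A", "C"),
    "GC": Transformation("G", "C"),
    "AT": Transformation("A", "T"),
}


def reduce_alphabet(seq: str, t: Transformation) -> str:
    """Apply the reduction: every source base becomes the target base.

    All other characters, including N and lower case, are left unchanged;
    length is preserved.  Idempotent.
    """
    return seq.replace(t.source_base, t.target_base)


@dataclass(frozen=True)
class TransformationCombo:
    """One (reduction, DNA strand, RNA strand) alignment configuration.

    ``effective_transformation`` is the reduction applied to the + genome when
    the alignment is carried out entirely in +-genome orientation: aligning to
    the reduced − strand is equivalent to aligning the reverse-complemented
    read against the + strand reduced with the complementary substitution.
    ``oriented_rc`` says whether the read must be reverse-complemented to lie
    in +-genome orientation under this combo.
    """

    combo_id: str
    transformation: Transformation
    dna_strand: str
    rna_strand: str
    detectable_types: frozenset[str] = field(hash=False)

    @property
    def effective_transformation(self) -> Transformation:
        if self.dna_strand == "+":
            return self.transformation
        return self.transformation.complement()

    @property
    def oriented_rc(self) -> bool:
        # read is RC'd once for RNA−, and once more when mapping a −-DNA
        # alignment back onto the + genome
        return (self.rna_strand == "-") != (self.dna_strand == "-")


def enumerate_combos() -> list[TransformationCombo]:
    """The canonical, ordered list of the 12 transformation/strand combos.

    Order: (A→G, A→C, G→C, A→T) × (DNA+/RNA+, DNA+/RNA−, DNA−/RNA+,
    DNA−/RNA−), with the redundant DNA− combos of the complement-symmetric
    G→C and A→T dropped.  Ids are stable strings like ``AG_p_m``.
    """
    strand_code = {"+": "p", "-": "m"}
    combos: list[TransformationCombo] = []
    for tid in ("AG", "AC", "GC", "AT"):
        t = TRANSFORMATIONS[tid]
        symmetric = t.masked_types() == t.complement().masked_types()
        for dna in ("+", "-"):
            if dna == "-" and symmetric:
                continue
            for rna in ("+", "-"):
                eff = t if dna == "+" else t.complement()
                combos.append(
                    TransformationCombo(
                        combo_id=f"{tid}_{strand_code[dna]}_{strand_code[rna]}",
                        transformation=t,
                        dna_strand=dna,
                        rna_strand=rna,
                        detectable_types=eff.masked_types(),
                    )
                )
    return combos


def masked_equal(dna: str, rna: str, t: Transformation) -> bool:
    """True iff the two equal-length sequences match after reduction.

    Equivalently: every mismatching column is one of the two reciprocal types
    masked by ``t``.
    """
    if len(dna) != len(rna):
        raise ValueError("masked_equal requires equal-length sequences")
    return reduce_alphabet(dna, t) == reduce_alphabet(rna, t)


def combo_table() -> "list[dict[str, str]]":
    """The combo enumeration as rows (id, transformation, strands, types)."""
    rows = []
    for c in enumerate_combos():
        rows.append(
            {
                "combo_id": c.combo_id,
                "transformation": c.transformation.name,
                "dna_strand": c.dna_strand,
                "rna_strand": c.rna_strand,
                "detectable_types": ",".join(sorted(c.detectable_types)),
            }
        )
    return rows
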