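"""Glycopeptide identifiers and monoisotopic mass arithmetic.

N-glycopeptides are written as ``PEPTIDE_h_n_f_s`` where the four integers
count Hex, HexNAc, Fuc and Sia (NeuAc) residues — e.g.
``VCQDCPLLAPLNDTR_5_4_1_2`` is a bi-antennary, disialylated glycan with one
fucose on the peptide VCQDCPLLAPLNDTR.

The module computes theoretical m/z values for the 14 diagnostic glycosidic
fragment ions used to classify fucosylation: six glycan-only oxonium B ions
(B2, B2F, B3, B3F, B3S, B3SF) and eight peptide-bearing Y ions
(Y1..Y4 and their fucosylated partners Y1F..Y4F).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from pyteomics.mass import std_aa_mass


class GlycopeptideParseError(ValueError):
    """Raised when a glycopeptide ID string cannot be parsed."""


@dataclass(frozen=True)
class MonosaccharideMasses:
    """Monoisotopic residue masses (Da) for the four glycan building blocks."""

    hex: float = 162.05282
    hexnac: float = 203.07937
    fuc: float = 146.05791
    neuac: float = 291.09542
    proton: float = 1.00728
    water: float = 18.01056


MASSES = MonosaccharideMasses()

#: Fixed modifications applied to peptide masses by default: carbamidomethyl
#: cysteine (iodoacetamide alkylation).
DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": 57.02146}

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of Hex / HexNAc / Fuc / Sia residues in an N-glycan."""

    n_hex: int = 0
    n_hexnac: int = 0
    n_fuc: int = 0
    n_sia: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hex", "n_hexnac", "n_fuc", "n_sia"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    def residue_mass(self, masses: MonosaccharideMasses = MASSES) -> float:
        """Sum of glycan residue masses (Da), no water, no charge."""
        return (
            self.n_hex * masses.hex
            + self.n_hexnac * masses.hexnac
            + self.n_fuc * masses.fuc
            + self.n_sia * masses.neuac
        )

    def contains(self, other: "GlycanComposition") -> bool:
        """True if ``other`` fits component-wise within this composition."""
        return (
            self.n_hex >= other.n_hex
            and self.n_hexnac >= other.n_hexnac
            and self.n_fuc >= other.n_fuc
            and self.n_sia >= other.n_sia
        )


@dataclass(frozen=True)
class GlycopeptideID:
    """A peptide backbone plus its glycan composition."""

    peptide: str
    composition: GlycanComposition

    def __str__(self) -> str:
        return format_glycopeptide_id(self)


@dataclass(frozen=True)
class FragmentSpec:
    """One diagnostic fragment: its label, glycan part and whether the
    peptide backbone is retained (Y series) or not (B series / oxonium)."""

    ion_label: str
    glycan_part: GlycanComposition
    includes_peptide: bool


#: Fixed panel order of the 14 diagnostic ions.
DIAGNOSTIC_ION_ORDER: tuple[str, ...] = (
    "B2", "B2F", "B3", "B3F", "B3S", "B3SF",
    "Y1", "Y1F", "Y2", "Y2F", "Y3", "Y3F", "Y4", "Y4F",
)

#: Ions whose presence evidences outer (antenna) fucosylation.
B_FUC_IONS: tuple[str, ...] = ("B2F", "B3F", "B3SF")
#: Ions whose presence evidences core fucosylation.
Y_FUC_IONS: tuple[str, ...] = ("Y1F", "Y2F", "Y3F", "Y4F")


def _gc(h: int = 0, n: int = 0, f: int = 0, s: int = 0) -> GlycanComposition:
    return GlycanComposition(n_hex=h, n_hexnac=n, n_fuc=f, n_sia=s)


DIAGNOSTIC_FRAGMENTS: Mapping[str, FragmentSpec] = {
    "B2": FragmentSpec("B2", _gc(h=1, n=1), False),
    "B2F": FragmentSpec("B2F", _gc(h=1, n=1, f=1), False),
    "B3": FragmentSpec("B3", _gc(h=2, n=1), False),
    "B3F": FragmentSpec("B3F", _gc(h=2, n=1, f=1), False),
    "B3S": FragmentSpec("B3S", _gc(h=1, n=1, s=1), False),
    "B3SF": FragmentSpec("B3SF", _gc(h=1, n=1, f=1, s=1), False),
    "Y1": FragmentSpec("Y1", _gc(n=1), True),
    "Y1F": FragmentSpec("Y1F", _gc(n=1, f=1), True),
    "Y2": FragmentSpec("Y2", _gc(n=2), True),
    "Y2F": FragmentSpec("Y2F", _gc(n=2, f=1), True),
    "Y3": FragmentSpec("Y3", _gc(h=1, n=2), True),
    "Y3F": FragmentSpec("Y3F", _gc(h=1, n=2, f=1), True),
    "Y4": FragmentSpec("Y4", _gc(h=2, n=2), True),
    "Y4F": FragmentSpec("Y4F", _gc(h=2, n=2, f=1), True),
}


def parse_glycopeptide_id(id_string: str) -> GlycopeptideID:
    """Parse ``PEPTIDE_h_n_f_s`` into peptide + composition.

    The four integer suffixes count Hex, HexNAc, Fuc and Sia in that order.

    >>> gp = parse_glycopeptide_id("VCQDCPLLAPLNDTR_5_4_1_2")
    >>> gp.composition.n_fuc
    1
    """
    tokens = id_string.split("_")
    if len(tokens) != 5:
        raise GlycopeptideParseError(
            f"expected PEPTIDE plus four integer counts, got {len(tokens)} "
            f"underscore-separated tokens in {id_string!r}"
        )
    peptide = tokens[0]
    if not peptide:
        raise GlycopeptideParseError(f"empty peptide in {id_string!r}")
    bad = set(peptide) - _VALID_RESIDUES
    if bad:
        raise GlycopeptideParseError(
            f"peptide {peptide!r} contains non-standard residue(s) {sorted(bad)}"
        )
    counts = []
    for tok in tokens[1:]:
        if not tok.isdigit():
            raise GlycopeptideParseError(
                f"composition token {tok!r} in {id_string!r} is not a "
                "non-negative integer"
            )
        counts.append(int(tok))
    return GlycopeptideID(peptide, GlycanComposition(*counts))


def format_glycopeptide_id(gp: GlycopeptideID) -> str:
    c = gp.composition
    return f"{gp.peptide}_{c.n_hex}_{c.n_hexnac}_{c.n_fuc}_{c.n_sia}"


def peptide_mass(
    peptide: str,
    fixed_mods: Mapping[str, float] = DEFAULT_FIXED_MODS,
) -> float:
    """Monoisotopic neutral mass of a peptide with fixed modifications.

    Defaults to carbamidomethylated cysteines (+57.02146 Da).
    """
    if not peptide:
        raise ValueError("empty peptide")
    total = MASSES.water
    for aa in peptide:
        try:
            total += std_aa_mass[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue {aa!r}") from None
        total += fixed_mods.get(aa, 0.0)
    return total


def fragment_mz(
    spec: FragmentSpec,
    peptide: str | None = None,
    charge: int = 1,
    fixed_mods: Mapping[str, float] = DEFAULT_FIXED_MODS,
) -> float:
    """Theoretical m/z of a diagnostic fragment.

    B ions are glycan oxonium cations: (sum of residue masses + z protons)/z.
    Y ions retain the intact peptide: the peptide neutral mass is added.
    """
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    neutral = spec.glycan_part.residue_mass()
    if spec.includes_peptide:
        if peptide is None:
            raise ValueError(f"Y-series ion {spec.ion_label} requires a peptide")
        neutral += peptide_mass(peptide, fixed_mods)
    return (neutral + charge * MASSES.proton) / charge


def diagnostic_ion_set(
    gp: GlycopeptideID,
    charge: int = 1,
    fixed_mods: Mapping[str, float] = DEFAULT_FIXED_MODS,
) -> list[tuple[str, float]]:
    """The 14 (ion label, theoretical m/z) pairs for one glycopeptide,
    in fixed panel order."""
    return [
        (label, fragment_mz(DIAGNOSTIC_FRAGMENTS[label], gp.peptide, charge, fixed_mods))
        for label in DIAGNOSTIC_ION_ORDER
    ]


def feasible_ions(gp: GlycopeptideID) -> list[str]:
    """Diagnostic ions whose glycan part fits within the glycopeptide's
    composition (e.g. B3S requires at least one sialic acid)."""
    return [
        label
        for label in DIAGNOSTIC_ION_ORDER
        if gp.composition.contains(DIAGNOSTIC_FRAGMENTS[label].glycan_part)
    ]


def antennarity_class(composition: GlycanComposition) -> str:
    """Coarse antennary type of an N-glycan composition.

    HexNAc residues beyond the two core GlcNAcs are counted as antennae;
    a mannose excess (Hex >= antennae + 4) with at least one antenna flags
    a hybrid structure. Returns one of ``mono``, ``bi``, ``tri_tetra``,
    ``hybrid``, ``other``.
    """
    antennae = composition.n_hexnac - 2
    if antennae >= 1 and composition.n_hex >= antennae + 4:
        return "hybrid"
    if antennae == 1:
        return "mono"
    if antennae == 2:
        return "bi"
    if antennae in (3, 4):
        return "tri_tetra"
    return "other"
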