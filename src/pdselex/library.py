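"""Library designs, degenerate-codon statistics and IUPAC motif matching.

This module holds the static descriptions of the two starting libraries in a
library-vs-library selection: a hairpin RNA library whose loop is fully
randomized, and a protein library built on a fixed scaffold with a small set
of surface residues randomized through NNK degenerate codons (N = A/C/G/T,
K = G/T; 32 codons covering all 20 amino acids plus the amber stop).  It also
provides the IUPAC degenerate-motif matcher used for consensus-sequence
counting throughout the analysis.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources

import yaml
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_rna_values

__all__ = [
    "STOP_SYMBOL",
    "NNK_CODONS",
    "AminoAcidDistribution",
    "MotifPattern",
    "ProteinLibraryDesign",
    "RnaLibraryDesign",
    "canonical_rna",
    "combination_space",
    "encode_variable_region",
    "load_preset",
    "motif_match",
    "nnk_amino_acid_distribution",
    "nnk_codons_for",
    "theoretical_diversity",
    "translate_variable_region",
]

STOP_SYMBOL = "*"

#: the 32 NNK codons (DNA alphabet), enumeration order irrelevant to results
NNK_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", "ACGT", "GT")
)

_RNA_BASES = frozenset("ACGU")


def canonical_rna(sequence: str) -> str:
    """Uppercase and convert T to U. Does not validate."""
    return sequence.upper().replace("T", "U")


def _validate_rna(sequence: str, *, what: str = "sequence") -> str:
    seq = canonical_rna(sequence)
    for i, ch in enumerate(seq):
        if ch not in _RNA_BASES:
            raise ValueError(
                f"illegal character {ch!r} at position {i} in {what}"
            )
    return seq


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RnaLibraryDesign:
    """Hairpin RNA library: fixed flanks around a randomized loop.

    The 3' fixed region contains the docking sequence — the segment that
    hybridizes to the immobilized capture oligonucleotide in the second
    purification step — so the design checks it is a substring of ``fixed_3p``.
    """

    fixed_5p: str
    variable_length: int
    fixed_3p: str
    docking_sequence: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_5p", _validate_rna(self.fixed_5p, what="fixed_5p"))
        object.__setattr__(self, "fixed_3p", _validate_rna(self.fixed_3p, what="fixed_3p"))
        object.__setattr__(
            self, "docking_sequence", canonical_rna(self.docking_sequence)
        )
        if self.variable_length <= 0:
            raise ValueError("variable_length must be positive")
        if not self.fixed_5p or not self.fixed_3p:
            raise ValueError("fixed flanks must be nonempty")
        if self.docking_sequence and self.docking_sequence not in self.fixed_3p:
            raise ValueError("docking sequence must be a substring of fixed_3p")


@dataclass(frozen=True)
class ProteinLibraryDesign:
    """Scaffold protein with NNK-randomized surface residues.

    ``randomized_positions`` are 1-based residue indices into ``scaffold``.
    ``read_window`` is the 1-based inclusive residue range covered by a
    sequencing read of the variable region (in frame with the scaffold).
    """

    scaffold: str
    randomized_positions: tuple[int, ...]
    codon_scheme: str = "NNK"
    read_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scaffold", self.scaffold.upper())
        pos = tuple(self.randomized_positions)
        object.__setattr__(self, "randomized_positions", pos)
        if len(pos) != 8:
            raise ValueError("exactly 8 randomized positions are required")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("randomized positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > len(self.scaffold):
            raise ValueError("randomized positions must lie within the scaffold")
        if self.codon_scheme != "NNK":
            raise ValueError(f"unsupported codon scheme {self.codon_scheme!r}")
        if self.read_window is None:
            object.__setattr__(self, "read_window", (pos[0], pos[-1]))
        lo, hi = self.read_window
        if not (1 <= lo <= pos[0] and pos[-1] <= hi <= len(self.scaffold)):
            raise ValueError("read_window must cover all randomized positions")


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC degenerate RNA motif (e.g. UUGUGASGC with S = C or G)."""

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        pat = canonical_rna(self.pattern)
        for i, ch in enumerate(pat):
            if ch not in ambiguous_rna_values:
                raise ValueError(
                    f"illegal IUPAC RNA code {ch!r} at position {i} in pattern"
                )
        object.__setattr__(self, "pattern", pat)

    @property
    def regex(self) -> re.Pattern[str]:
        parts = []
        for ch in self.pattern:
            expansion = ambiguous_rna_values[ch]
            parts.append(expansion if len(expansion) == 1 else f"[{expansion}]")
        return re.compile("".join(parts))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.pattern


@dataclass(frozen=True)
class AminoAcidDistribution:
    """Probability distribution over the 20 amino acids plus stop ('*')."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        if any(p < 0 for p in probs.values()):
            raise ValueError("probabilities must be nonnegative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        object.__setattr__(self, "probabilities", probs)

    def __getitem__(self, residue: str) -> float:
        return self.probabilities.get(residue, 0.0)

    def modal_residues(self) -> set[str]:
        """Residues attaining the maximum probability."""
        top = max(self.probabilities.values())
        return {r for r, p in self.probabilities.items() if p == top}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _translate_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if codon in standard_dna_table.stop_codons:
        return STOP_SYMBOL
    try:
        return standard_dna_table.forward_table[codon]
    except KeyError as exc:
        raise ValueError(f"cannot translate codon {codon!r}") from exc


def nnk_amino_acid_distribution() -> AminoAcidDistribution:
    """Amino-acid distribution induced by NNK codons, each of weight 1/32.

    The amber stop (TAG) is the only stop codon consistent with NNK, so
    P(stop) = 1/32; arginine, leucine and serine are modal at 3/32 each.
    """
    counts: dict[str, int] = {}
    for codon in NNK_CODONS:
        aa = _translate_codon(codon)
        counts[aa] = counts.get(aa, 0) + 1
    n = len(NNK_CODONS)
    return AminoAcidDistribution({aa: c / n for aa, c in counts.items()})


def nnk_codons_for(residue: str) -> tuple[str, ...]:
    """All NNK codons (DNA) encoding ``residue`` ('*' for stop)."""
    return tuple(c for c in NNK_CODONS if _translate_codon(c) == residue)


def theoretical_diversity(n_positions: int, alphabet_size: int) -> int:
    """alphabet_size ** n_positions, as an exact Python integer."""
    if n_positions < 0:
        raise ValueError("n_positions must be >= 0")
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be >= 1")
    return alphabet_size**n_positions


def combination_space(rna_diversity, protein_diversity):
    """Number of possible RNA-protein combinations (simple product)."""
    if rna_diversity < 0 or protein_diversity < 0:
        raise ValueError("diversities must be nonnegative")
    return rna_diversity * protein_diversity


def motif_match(sequence: str, pattern: MotifPattern | str) -> bool:
    """True iff some ungapped window of ``sequence`` matches ``pattern``.

    Matching is case-insensitive; T is treated as U on input.
    """
    if not isinstance(pattern, MotifPattern):
        pattern = MotifPattern(pattern)
    seq = _validate_rna(sequence)
    return pattern.regex.search(seq) is not None


def translate_variable_region(dna_read: str, design: ProteinLibraryDesign) -> str:
    """Translate the randomized residues from a read of the variable region.

    The read is assumed to start, in frame, at the first residue of
    ``design.read_window``.  Stop codons are reported as ``'*'``.  Reads too
    short to cover every randomized codon (or out of frame by length) are
    rejected.
    """
    lo, hi = design.read_window
    n_res = hi - lo + 1
    read = dna_read.upper().replace("U", "T")
    if len(read) < 3 * n_res:
        raise ValueError(
            f"read of length {len(read)} does not cover the {n_res}-residue "
            f"window (need {3 * n_res} nt)"
        )
    out = []
    for pos in design.randomized_positions:
        off = (pos - lo) * 3
        out.append(_translate_codon(read[off : off + 3]))
    return "".join(out)


def encode_variable_region(
    residues: str, design: ProteinLibraryDesign, rng
) -> str:
    """DNA for the read window with ``residues`` at the randomized positions.

    Non-randomized scaffold residues are back-translated with an arbitrary
    fixed codon choice; randomized positions get a random NNK-consistent
    codon.  Used by the simulator to build sequencing-read templates.
    """
    if len(residues) != len(design.randomized_positions):
        raise ValueError("residue string length must match randomized positions")
    lo, hi = design.read_window
    rand_at = dict(zip(design.randomized_positions, residues))
    codons = []
    for pos in range(lo, hi + 1):
        if pos in rand_at:
            options = nnk_codons_for(rand_at[pos])
            if not options:
                raise ValueError(f"no NNK codon encodes {rand_at[pos]!r}")
            codons.append(options[int(rng.integers(len(options)))])
        else:
            aa = design.scaffold[pos - 1]
            codons.append(_BACK_TABLE[aa])
    return "".join(codons)


# one fixed sense codon per amino acid, for back-translating scaffold residues
_BACK_TABLE: dict[str, str] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _BACK_TABLE.setdefault(_aa, _codon)
_BACK_TABLE[STOP_SYMBOL] = "TAG"


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def load_preset(name: str = "default"):
    """Load a library-design preset shipped with the package.

    Returns ``(RnaLibraryDesign, ProteinLibraryDesign)``.  Presets are plain
    YAML key-value files under ``pdselex/presets``; users can supply their own
    files with the same keys via :func:`load_preset_file`.
    """
    path = resources.files("pdselex.presets").joinpath(f"{name}.yaml")
    with path.open("r") as fh:
        return _designs_from_mapping(yaml.safe_load(fh))


def load_preset_file(path):
    with open(path) as fh:
        return _designs_from_mapping(yaml.safe_load(fh))


def _designs_from_mapping(cfg: dict):
    rna = cfg["rna_library"]
    prot = cfg["protein_library"]
    rna_design = RnaLibraryDesign(
        fixed_5p=rna["fixed_5p"],
        variable_length=int(rna["variable_length"]),
        fixed_3p=rna["fixed_3p"],
        docking_sequence=rna.get("docking_sequence", ""),
    )
    protein_design = ProteinLibraryDesign(
        scaffold=prot["scaffold"],
        randomized_positions=tuple(prot["randomized_positions"]),
        codon_scheme=prot.get("codon_scheme", "NNK"),
        read_window=tuple(prot["read_window"]) if "read_window" in prot else None,
    )
    return rna_design, protein_design
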