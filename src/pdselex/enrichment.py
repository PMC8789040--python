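"""NGS enrichment analysis of selection pools.

Implements the read-level pipeline (demultiplexing, variable-region
extraction) and the pool-level statistics used to call enriched variants:
round-to-round enrichment factors (EF = relative abundance after / before),
the monotonic-EF filter, top-N ranking with a deterministic tie-break,
copy-number diversity binning, abundance-weighted consensus-motif fractions,
and positional residue preferences of ranked protein variants.

All sequence coordinates are 0-based half-open internally; relative
abundance, not raw count, is the EF numerator and denominator, making EFs
robust to differing sequencing depth per round.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import MotifPattern, RnaLibraryDesign, canonical_rna, motif_match

__all__ = [
    "CountTable",
    "DiversityProfile",
    "EnrichmentRecord",
    "ExtractionResult",
    "build_count_table",
    "demultiplex",
    "diversity_profile",
    "enrichment_factor",
    "enrichment_factors",
    "extract_variable_region",
    "filter_monotonic_enrichment",
    "motif_fraction",
    "positional_residue_frequency",
    "top_n",
]

DEFAULT_BIN_EDGES = (2, 10, 100, 1_000, 10_000, 100_000)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


class CountTable:
    """Per-sequence read counts keyed by (pool_id, round).

    The canonical ordering for every ranked output is count descending with
    ties broken by lexicographically smaller sequence first.
    """

    def __init__(self) -> None:
        self._counts: dict[tuple[str, int], pd.Series] = {}

    def add(self, pool: str, round_index: int, sequences) -> None:
        """Count a collection of sequences (or fold in a mapping of counts)."""
        if isinstance(sequences, (dict, Counter)):
            counter = Counter({k: int(v) for k, v in sequences.items()})
        elif isinstance(sequences, pd.Series):
            counter = Counter({k: int(v) for k, v in sequences.items()})
        else:
            counter = Counter(sequences)
        if sum(counter.values()) == 0:
            raise ValueError(
                f"empty input for pool {pool!r} round {round_index}"
            )
        key = (pool, int(round_index))
        if key in self._counts:
            counter.update(self._counts[key].to_dict())
        series = pd.Series(counter, dtype=np.int64)
        order = sorted(series.index, key=lambda s: (-series[s], s))
        self._counts[key] = series.loc[order]

    def counts(self, pool: str, round_index: int) -> pd.Series:
        key = (pool, int(round_index))
        if key not in self._counts:
            raise KeyError(f"no counts for pool {pool!r} round {round_index}")
        return self._counts[key]

    def abundance(self, pool: str, round_index: int) -> pd.Series:
        counts = self.counts(pool, round_index)
        return counts / counts.sum()

    def rounds(self, pool: str) -> list[int]:
        return sorted(r for p, r in self._counts if p == pool)

    def pools(self) -> list[str]:
        return sorted({p for p, _ in self._counts})

    def richness(self, pool: str, round_index: int) -> int:
        return int((self.counts(pool, round_index) > 0).sum())


def build_count_table(sequences_by_key: dict) -> CountTable:
    """Exact multiset counting per declared (pool, round).

    ``sequences_by_key`` maps ``(pool_id, round)`` to an iterable of
    sequences.  A declared but empty round is an error, not a silent empty
    table.
    """
    table = CountTable()
    for (pool, round_index), sequences in sequences_by_key.items():
        table.add(pool, round_index, sequences)
    return table


# ---------------------------------------------------------------------------
# read-level operations
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(records, barcode_map: dict[str, str], max_mismatch: int = 1):
    """Partition reads by leading barcode.

    Barcodes must be equal length with pairwise Hamming distance greater
    than ``2 * max_mismatch`` so that assignment within the tolerance is
    unique; the partition into barcode bins plus ``unassigned`` is
    exhaustive and disjoint.
    """
    barcodes = {k: v.upper().replace("U", "T") for k, v in barcode_map.items()}
    lengths = {len(v) for v in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    (bclen,) = lengths
    ids = list(barcodes)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = _hamming(barcodes[a], barcodes[b])
            if d <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {a!r} and {b!r} are Hamming distance {d} apart; "
                    f"need > {2 * max_mismatch} for max_mismatch={max_mismatch}"
                )
    bins: dict[str, list] = {k: [] for k in barcodes}
    bins["unassigned"] = []
    exact = {v: k for k, v in barcodes.items()}
    for rec in records:
        prefix = rec.sequence[:bclen].upper()
        hit = exact.get(prefix)
        if hit is None:
            for k, bc in barcodes.items():
                if _hamming(prefix, bc) <= max_mismatch:
                    hit = k
                    break
        bins[hit if hit is not None else "unassigned"].append(rec)
    return bins


@dataclass(frozen=True)
class ExtractionResult:
    sequence: str | None
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.sequence is not None


def _find_anchor(read: str, anchor: str, max_mismatch: int, start: int = 0) -> int:
    """Leftmost position of ``anchor`` in ``read`` within ``max_mismatch``
    substitutions, or -1."""
    pos = read.find(anchor, start)
    if pos >= 0:
        return pos
    if max_mismatch == 0:
        return -1
    n, m = len(read), len(anchor)
    for i in range(start, n - m + 1):
        if _hamming(read[i : i + m], anchor) <= max_mismatch:
            return i
    return -1


def extract_variable_region(
    read_sequence: str,
    design: RnaLibraryDesign,
    flank_anchor_len: int = 12,
    max_flank_mismatch: int = 1,
) -> ExtractionResult:
    """Pull the variable loop out of a read by anchoring on the fixed flanks.

    The anchor for the 5' flank is its 3'-most ``flank_anchor_len`` bases
    and for the 3' flank its 5'-most bases; each may carry up to
    ``max_flank_mismatch`` substitutions.  The enclosed subsequence is
    returned canonicalized to RNA (T -> U).  Failures carry a reason code.
    """
    read = read_sequence.upper().replace("U", "T")
    anchor5 = design.fixed_5p[-flank_anchor_len:].replace("U", "T")
    anchor3 = design.fixed_3p[:flank_anchor_len].replace("U", "T")
    if len(read) < len(anchor5) + len(anchor3) + 1:
        return ExtractionResult(None, "read_too_short")
    p5 = _find_anchor(read, anchor5, max_flank_mismatch)
    if p5 < 0:
        return ExtractionResult(None, "flank_not_found")
    insert_start = p5 + len(anchor5)
    p3 = _find_anchor(read, anchor3, max_flank_mismatch, start=insert_start)
    if p3 < 0:
        return ExtractionResult(None, "flank_not_found")
    if p3 == insert_start:
        return ExtractionResult(None, "empty_insert")
    return ExtractionResult(canonical_rna(read[insert_start:p3]))


# ---------------------------------------------------------------------------
# enrichment factors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentRecord:
    species: str
    round_from: int
    round_to: int
    ef: float | None  # None <=> undefined (absent before)

    @property
    def defined(self) -> bool:
        return self.ef is not None


def enrichment_factor(
    table: CountTable, species: str, pool: str, round_to: int
) -> EnrichmentRecord:
    """EF = abundance at ``round_to`` / abundance at ``round_to - 1``.

    A species absent (or zero) in the earlier round has an undefined EF,
    which is distinct from EF = 0 (present before, absent after).
    """
    round_from = round_to - 1
    before = table.abundance(pool, round_from)
    after = table.abundance(pool, round_to)
    a0 = float(before.get(species, 0.0))
    if a0 == 0.0:
        return EnrichmentRecord(species, round_from, round_to, None)
    a1 = float(after.get(species, 0.0))
    return EnrichmentRecord(species, round_from, round_to, a1 / a0)


def enrichment_factors(
    table: CountTable, pool: str, round_to: int
) -> pd.Series:
    """Vector of EFs into ``round_to`` for every species present in the
    earlier round (undefined EFs are simply not represented)."""
    before = table.abundance(pool, round_to - 1)
    after = table.abundance(pool, round_to)
    before = before[before > 0]
    return after.reindex(before.index, fill_value=0.0) / before


def filter_monotonic_enrichment(
    table: CountTable,
    pool: str,
    rounds: tuple[int, int, int],
    threshold: float = 1.0,
) -> set[str]:
    """Species whose EFs across both consecutive transitions are defined and
    >= ``threshold`` (boundary inclusive)."""
    r1, r2, r3 = rounds
    if not (r2 == r1 + 1 and r3 == r2 + 1):
        raise ValueError("rounds must be three consecutive round indices")
    ef12 = enrichment_factors(table, pool, r2)
    ef23 = enrichment_factors(table, pool, r3)
    keep = set()
    for species in ef12.index.intersection(ef23.index):
        if ef12[species] >= threshold and ef23[species] >= threshold:
            keep.add(species)
    return keep


def top_n(table: CountTable, pool: str, round_index: int, n: int = 20) -> list[str]:
    """First ``n`` species by count (ties: lexicographically smaller first).

    If the pool has fewer than ``n`` species, all are returned with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = table.counts(pool, round_index)
    if len(counts) < n:
        warnings.warn(
            f"pool {pool!r} round {round_index} has only {len(counts)} species "
            f"(requested top {n})",
            stacklevel=2,
        )
    return list(counts.index[:n])


# ---------------------------------------------------------------------------
# pool-level summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiversityProfile:
    """Copy-number composition of a pool: per-bin population proportion and
    unique-sequence count, with singletons in their own bin."""

    labels: tuple[str, ...]
    proportions: tuple[float, ...]
    unique_counts: tuple[int, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.labels,
                "proportion": self.proportions,
                "unique_sequences": self.unique_counts,
            }
        )


def diversity_profile(
    table: CountTable,
    pool: str,
    round_index: int,
    bin_edges=DEFAULT_BIN_EDGES,
) -> DiversityProfile:
    """Bin species by copy count: a singleton bin (count == 1) plus
    half-open multi-copy bins [e_k, e_{k+1}) ending with [e_last, inf)."""
    edges = list(bin_edges)
    if edges != sorted(set(edges)):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] != 2:
        raise ValueError("first multi-copy bin must start at 2")
    counts = table.counts(pool, round_index)
    counts = counts[counts > 0]
    total = counts.sum()
    labels = ["singleton"]
    proportions = [float(counts[counts == 1].sum() / total)]
    uniques = [int((counts == 1).sum())]
    bounds = edges + [math.inf]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        in_bin = (counts >= lo) & (counts < hi)
        labels.append(f"[{lo},{'inf' if hi is math.inf else hi})")
        proportions.append(float(counts[in_bin].sum() / total))
        uniques.append(int(in_bin.sum()))
    return DiversityProfile(tuple(labels), tuple(proportions), tuple(uniques))


def motif_fraction(
    table: CountTable, pool: str, round_index: int, pattern: MotifPattern | str
) -> float:
    """Abundance-weighted fraction of the population containing the motif."""
    if not isinstance(pattern, MotifPattern):
        pattern = MotifPattern(pattern)
    abundance = table.abundance(pool, round_index)
    regex = pattern.regex
    mask = [regex.search(canonical_rna(seq)) is not None for seq in abundance.index]
    return float(abundance[mask].sum())


def positional_residue_frequency(
    ranked_sequences: list[str],
    top_k: int,
    weights=None,
    positions: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Per-position residue frequencies among the top-k ranked variants.

    Rows are residue symbols, columns are positions (labelled with the
    1-based scaffold residue numbers if ``positions`` is given, else 1..L).
    ``weights`` switches from unweighted to abundance-weighted frequencies.
    """
    if top_k < 1 or top_k > len(ranked_sequences):
        raise ValueError("top_k must be in [1, len(ranked_sequences)]")
    seqs = ranked_sequences[:top_k]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all sequences must have equal length")
    (length,) = lengths
    if positions is None:
        positions = tuple(range(1, length + 1))
    if len(positions) != length:
        raise ValueError("positions must label every residue")
    if weights is None:
        w = np.ones(top_k)
    else:
        w = np.asarray(list(weights)[:top_k], dtype=float)
        if len(w) != top_k or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    residues = sorted({ch for s in seqs for ch in s})
    out = pd.DataFrame(0.0, index=residues, columns=list(positions))
    for seq, wi in zip(seqs, w):
        for pos_label, ch in zip(positions, seq):
            out.loc[ch, pos_label] += wi
    return out


# ---------------------------------------------------------------------------
# pipeline conveniences
# ---------------------------------------------------------------------------


def count_rna_reads(
    records,
    design: RnaLibraryDesign,
    barcode_len: int = 0,
    flank_anchor_len: int = 12,
    max_flank_mismatch: int = 1,
):
    """Extract variable regions from RNA reads; returns (sequences, rejects).

    ``barcode_len`` leading bases are stripped before anchoring (reads may
    instead be pre-demultiplexed, in which case leave it 0 — the 5' anchor
    search tolerates a leading barcode anyway).
    """
    sequences: list[str] = []
    rejects: Counter = Counter()
    for rec in records:
        res = extract_variable_region(
            rec.sequence[barcode_len:], design, flank_anchor_len, max_flank_mismatch
        )
        if res.ok:
            sequences.append(res.sequence)
        else:
            rejects[res.reason] += 1
    return sequences, rejects


def count_protein_reads(
    records,
    design,
    barcode_len: int = 0,
    keep_stops: bool = False,
):
    """Translate protein-pool reads to randomized 8-mers.

    Reads whose translation contains a stop codon correspond to
    non-displayed variants and are excluded by default (``keep_stops``
    retains them).  Returns (eight_mers, rejects).
    """
    from .library import STOP_SYMBOL, translate_variable_region

    sequences: list[str] = []
    rejects: Counter = Counter()
    for rec in records:
        try:
            aa = translate_variable_region(rec.sequence[barcode_len:], design)
        except ValueError:
            rejects["untranslatable"] += 1
            continue
        if STOP_SYMBOL in aa and not keep_stops:
            rejects["stop_codon"] += 1
            continue
        sequences.append(aa)
    return sequences, rejects
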