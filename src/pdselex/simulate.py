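"""Stochastic simulator of library-vs-library selection campaigns.

The simulator reproduces the statistical structure of a two-step affinity
purification round: RNAs are captured on phage-displaying beads in proportion
to their equilibrium occupancy against the abundance-weighted displayed
protein mixture (step 1), then phage are retained according to whether they
are complexed with a captured RNA via the docking-sequence pulldown (step 2).
Each round applies binomial thinning per species, an optional negative
selection, a multinomial bottleneck, and lognormal amplification bias, and
can emit barcoded FASTQ reads with substitution errors.

Binding strength is held in a sparse :class:`KdLandscape`; pairs absent from
the landscape default to "no specific binding" (or to a global weak
``default_kd``).  Multivalent display (about 10 protein copies per virion)
is modelled as a phenomenological apparent-K_D division, and chaotrope
(urea) stringency as a multiplicative K_D penalty.

Every stochastic path is driven by a caller-supplied ``numpy.random.Generator``
so that a single seed reproduces a campaign byte-for-byte; an expectation
mode replaces all sampling with exact expected counts for analytic checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .library import (
    MotifPattern,
    ProteinLibraryDesign,
    RnaLibraryDesign,
    encode_variable_region,
)

__all__ = [
    "CampaignConfig",
    "CampaignResult",
    "KdLandscape",
    "Pool",
    "RoundConfig",
    "RoundResult",
    "SelectionCrash",
    "amplify",
    "avidity_adjusted_kd",
    "capture_probability",
    "default_campaign_schedule",
    "equilibrium_bound_fraction",
    "generate_reads",
    "mock_mixture_study",
    "planted_pair_study",
    "simulate_campaign",
    "simulate_round",
]


class SelectionCrash(RuntimeError):
    """A selection round retained nothing; carries the failing round index."""

    def __init__(self, round_index: int, pool_kind: str):
        self.round_index = round_index
        self.pool_kind = pool_kind
        super().__init__(
            f"selection crashed at round {round_index}: empty {pool_kind} pool"
        )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class KdLandscape:
    """Sparse (rna_id, protein_id) -> (k_on [1/(M s)], k_off [1/s]) map.

    Pairs absent from the map have no specific binding unless ``default_kd``
    (in M) is set, in which case every absent pair binds with that weak
    affinity.  K_D is always derived as k_off / k_on.
    """

    rates: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    default_kd: float | None = None

    def add(self, rna_id: str, protein_id: str, k_on: float, k_off: float) -> None:
        if k_on <= 0 or k_off <= 0:
            raise ValueError("rate constants must be strictly positive")
        self.rates[(rna_id, protein_id)] = (float(k_on), float(k_off))

    def kd(self, rna_id: str, protein_id: str) -> float | None:
        pair = self.rates.get((rna_id, protein_id))
        if pair is None:
            return self.default_kd
        k_on, k_off = pair
        return k_off / k_on

    def items(self):
        return self.rates.items()


@dataclass
class Pool:
    """A population of RNA or phage-displayed protein species.

    ``sequences`` holds the canonical variable region (RNA loop as RNA
    string, protein as the 8 randomized residues); ``templates`` the DNA
    read template used for sequencing simulation.
    """

    kind: str  # "rna" or "protein"
    ids: list[str]
    sequences: list[str]
    counts: np.ndarray
    templates: list[str] | None = None
    bead_binder: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rna", "protein"):
            raise ValueError("pool kind must be 'rna' or 'protein'")
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.bead_binder is None:
            self.bead_binder = np.zeros(len(self.ids), dtype=bool)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def abundances(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total

    def with_counts(self, counts: np.ndarray) -> "Pool":
        return dataclasses.replace(self, counts=np.asarray(counts, dtype=float))

    def index_of(self, species_id: str) -> int:
        try:
            return self.ids.index(species_id)
        except ValueError as exc:
            raise KeyError(f"unknown species {species_id!r}") from exc


@dataclass
class RoundConfig:
    """Stringency schedule for one selection round.

    ``effective_protein_conc`` (M) is the single effective concentration at
    which the bead-displayed protein mixture is presented to the RNA pool;
    ``effective_rna_conc`` plays the symmetric role for step-2 complexation
    and defaults to the protein value.  Backgrounds are per-molecule
    nonspecific retention probabilities, attenuated by ``(1 - wash_loss)``
    per wash; the RNase H elution acts as a further multiplier on the step-2
    background (``rnaseh_specificity``).
    """

    rna_input: float = 1e6
    phage_input: float = 1e6
    binding_time: float = 1800.0  # s; recorded, not modelled kinetically
    n_washes: int = 3
    urea: bool = False
    negative_selection: bool = False
    effective_protein_conc: float = 1e-9
    effective_rna_conc: float | None = None
    avidity_copies: int = 10
    avidity_exponent: float = 1.0
    urea_penalty: float = 5.0
    capture_eff_step1: float = 0.5
    capture_eff_step2: float = 0.5
    background_step1: float = 1e-4
    background_step2: float = 1e-4
    rnaseh_specificity: float = 0.1
    wash_loss: float = 0.5
    bottleneck_rna: int | None = None
    bottleneck_phage: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "capture_eff_step1",
            "capture_eff_step2",
            "background_step1",
            "background_step2",
            "wash_loss",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.avidity_copies < 1:
            raise ValueError("avidity_copies must be >= 1")
        if self.n_washes < 0:
            raise ValueError("n_washes must be >= 0")
        if self.effective_rna_conc is None:
            self.effective_rna_conc = self.effective_protein_conc


@dataclass
class CampaignConfig:
    """An ordered multi-round selection campaign."""

    rounds: list[RoundConfig]
    rna_design: RnaLibraryDesign | None = None
    protein_design: ProteinLibraryDesign | None = None
    reads_per_round: int = 0
    per_base_error_rate: float = 0.001
    rna_barcodes: list[str] | None = None  # one per sequenced pool (round 0..N)
    protein_barcodes: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.rounds) < 1:
            raise ValueError("a campaign needs at least one round")


@dataclass
class RoundResult:
    captured_rna: Pool
    captured_phage: Pool
    crashed: bool
    crashed_pool: str | None
    log: dict


@dataclass
class CampaignResult:
    """Per-round pools (index 0 is the input library) plus reads and truth."""

    rna_pools: list[Pool]
    phage_pools: list[Pool]
    round_logs: list[dict]
    rna_reads: dict[int, list]  # round -> FASTQ records (if reads requested)
    protein_reads: dict[int, list]
    landscape: KdLandscape
    truth: dict


# ---------------------------------------------------------------------------
# elementary binding model
# ---------------------------------------------------------------------------


def equilibrium_bound_fraction(kd: float, conc: float) -> float:
    """Single-site equilibrium occupancy: conc / (conc + kd)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if conc < 0:
        raise ValueError("conc must be nonnegative")
    return conc / (conc + kd)


def avidity_adjusted_kd(
    kd: float,
    copies: int = 10,
    urea: bool = False,
    avidity_exponent: float = 1.0,
    urea_penalty: float = 5.0,
) -> float:
    """Apparent K_D under multivalent display and optional urea stringency.

    Displaying ``copies`` protein copies per virion divides the apparent K_D
    by ``copies ** avidity_exponent``; urea multiplies it by ``urea_penalty``.
    Both are acknowledged phenomenological stand-ins.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    out = kd / copies**avidity_exponent
    if urea:
        out *= urea_penalty
    return out


def _apparent_inv_kd(kd: float | None, cfg: RoundConfig) -> float:
    """1 / apparent K_D, with None (no binding) mapping to 0."""
    if kd is None:
        return 0.0
    return 1.0 / avidity_adjusted_kd(
        kd,
        copies=cfg.avidity_copies,
        urea=cfg.urea,
        avidity_exponent=cfg.avidity_exponent,
        urea_penalty=cfg.urea_penalty,
    )


def _mixture_occupancy(
    query_ids: list[str],
    partner_pool: Pool,
    landscape: KdLandscape,
    cfg: RoundConfig,
    conc: float,
    query_is_rna: bool,
) -> np.ndarray:
    """Equilibrium bound fraction of each query species against the
    abundance-weighted partner mixture at total effective concentration
    ``conc``: theta = S / (1 + S) with S = conc * sum_j w_j / Kd_app(q, j).
    """
    weights = partner_pool.abundances
    base_inv = _apparent_inv_kd(landscape.default_kd, cfg)
    s = np.full(len(query_ids), float(weights.sum()) * base_inv)
    if landscape.rates:
        qindex = {q: i for i, q in enumerate(query_ids)}
        pindex = {p: j for j, p in enumerate(partner_pool.ids)}
        for (rna_id, prot_id), (k_on, k_off) in landscape.items():
            q_id, p_id = (rna_id, prot_id) if query_is_rna else (prot_id, rna_id)
            qi = qindex.get(q_id)
            pj = pindex.get(p_id)
            if qi is None or pj is None:
                continue
            s[qi] += weights[pj] * (_apparent_inv_kd(k_off / k_on, cfg) - base_inv)
    s *= conc
    return s / (1.0 + s)


def capture_probability(
    rna_id: str,
    phage_pool: Pool,
    landscape: KdLandscape,
    cfg: RoundConfig,
) -> float:
    """Probability that one molecule of ``rna_id`` survives step 1.

    Specific capture is ``capture_eff_step1`` times the occupancy against the
    displayed-protein mixture (apparent, avidity/urea adjusted); nonspecific
    background is attenuated by ``(1 - wash_loss)`` per wash.
    """
    theta = _mixture_occupancy(
        [rna_id],
        phage_pool,
        landscape,
        cfg,
        cfg.effective_protein_conc,
        query_is_rna=True,
    )[0]
    background = cfg.background_step1 * (1.0 - cfg.wash_loss) ** cfg.n_washes
    return min(1.0, cfg.capture_eff_step1 * theta + background)


def _step1_probabilities(
    rna_pool: Pool, phage_pool: Pool, landscape: KdLandscape, cfg: RoundConfig
) -> np.ndarray:
    theta = _mixture_occupancy(
        rna_pool.ids,
        phage_pool,
        landscape,
        cfg,
        cfg.effective_protein_conc,
        query_is_rna=True,
    )
    background = cfg.background_step1 * (1.0 - cfg.wash_loss) ** cfg.n_washes
    return np.minimum(1.0, cfg.capture_eff_step1 * theta + background)


def _step2_probabilities(
    phage_pool: Pool, captured_rna: Pool, landscape: KdLandscape, cfg: RoundConfig
) -> np.ndarray:
    theta = _mixture_occupancy(
        phage_pool.ids,
        captured_rna,
        landscape,
        cfg,
        cfg.effective_rna_conc,
        query_is_rna=False,
    )
    background = (
        cfg.background_step2
        * cfg.rnaseh_specificity
        * (1.0 - cfg.wash_loss) ** cfg.n_washes
    )
    return np.minimum(1.0, cfg.capture_eff_step2 * theta + background)


# ---------------------------------------------------------------------------
# round / amplification / campaign
# ---------------------------------------------------------------------------


def _thin(counts: np.ndarray, p: np.ndarray, mode: str, rng) -> np.ndarray:
    if mode == "expectation":
        return counts * p
    return rng.binomial(np.round(counts).astype(np.int64), p).astype(float)


def _bottleneck(counts: np.ndarray, limit: int | None, mode: str, rng) -> np.ndarray:
    total = counts.sum()
    if limit is None or total <= limit or total == 0:
        return counts
    if mode == "expectation":
        return counts * (limit / total)
    return rng.multinomial(int(limit), counts / total).astype(float)


def simulate_round(
    rna_pool: Pool,
    phage_pool: Pool,
    landscape: KdLandscape,
    cfg: RoundConfig,
    mode: str = "stochastic",
    rng: np.random.Generator | None = None,
) -> RoundResult:
    """One two-step purification round.

    In stochastic mode each molecule survives independently (binomial
    thinning) and pools are reduced to the configured bottlenecks by
    multinomial sampling; expectation mode returns exact expected counts.
    An empty post-selection pool is reported through ``crashed`` rather than
    as a silent zero.
    """
    if mode not in ("stochastic", "expectation"):
        raise ValueError("mode must be 'stochastic' or 'expectation'")
    if rna_pool.total == 0 or phage_pool.total == 0:
        raise ValueError("input pools must be nonempty")
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode requires an rng")

    rna_counts = rna_pool.counts.copy()
    phage_counts = phage_pool.counts.copy()
    if cfg.negative_selection:
        rna_counts[rna_pool.bead_binder] = 0.0
        phage_counts[phage_pool.bead_binder] = 0.0

    p1 = _step1_probabilities(
        rna_pool.with_counts(rna_counts), phage_pool.with_counts(phage_counts),
        landscape, cfg,
    )
    captured_rna_counts = _thin(rna_counts, p1, mode, rng)
    captured_rna_counts = _bottleneck(captured_rna_counts, cfg.bottleneck_rna, mode, rng)
    captured_rna = rna_pool.with_counts(captured_rna_counts)

    if captured_rna.total == 0:
        empty_phage = phage_pool.with_counts(np.zeros_like(phage_counts))
        return RoundResult(captured_rna, empty_phage, True, "rna", {"p1_mean": float(p1.mean())})

    p2 = _step2_probabilities(
        phage_pool.with_counts(phage_counts), captured_rna, landscape, cfg
    )
    captured_phage_counts = _thin(phage_counts, p2, mode, rng)
    captured_phage_counts = _bottleneck(
        captured_phage_counts, cfg.bottleneck_phage, mode, rng
    )
    captured_phage = phage_pool.with_counts(captured_phage_counts)

    crashed = captured_phage.total == 0
    log = {
        "p1_mean": float(p1.mean()),
        "p2_mean": float(p2.mean()),
        "rna_survivors": float(captured_rna.total),
        "phage_survivors": float(captured_phage.total),
    }
    return RoundResult(captured_rna, captured_phage, crashed,
                       "phage" if crashed else None, log)


def amplify(
    pool: Pool,
    target_total: float,
    amplification_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    mode: str = "stochastic",
) -> Pool:
    """Rescale a pool to ``target_total`` with lognormal per-species bias.

    With ``amplification_noise_sd = 0`` scaling is exactly proportional.
    Stochastic mode rounds each scaled count stochastically (floor plus a
    Bernoulli on the fractional part), so integer-valued targets of exact
    multiples are preserved exactly.
    """
    if pool.total == 0:
        raise ValueError("cannot amplify an empty pool")
    counts = pool.counts.astype(float)
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode requires an rng")
    weights = counts
    if amplification_noise_sd > 0 and mode == "stochastic":
        weights = counts * np.exp(
            rng.normal(0.0, amplification_noise_sd, size=counts.shape)
        )
    scaled = weights / weights.sum() * target_total
    if mode == "expectation":
        return pool.with_counts(scaled)
    floor = np.floor(scaled)
    frac = scaled - floor
    out = floor + (rng.random(scaled.shape) < frac)
    return pool.with_counts(out)


def simulate_campaign(
    campaign: CampaignConfig,
    rna_pool: Pool,
    phage_pool: Pool,
    landscape: KdLandscape,
    mode: str = "stochastic",
    rng: np.random.Generator | None = None,
    amplification_noise_sd: float = 0.1,
    truth: dict | None = None,
) -> CampaignResult:
    """Chain rounds of selection and amplification over a whole campaign.

    Emits per-round pools (index 0 is the input library) and, if
    ``campaign.reads_per_round > 0``, barcoded FASTQ records for every
    sequenced pool.  The binding landscape and any planted-pair annotations
    travel with the result as the ground truth for recovery tests.
    """
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode requires an rng")
    rna_pools = [rna_pool]
    phage_pools = [phage_pool]
    logs: list[dict] = []
    rna_reads: dict[int, list] = {}
    protein_reads: dict[int, list] = {}

    def _reads(pool: Pool, barcodes: list[str] | None, round_index: int):
        if campaign.reads_per_round <= 0:
            return None
        barcode = ""
        if barcodes is not None:
            barcode = barcodes[round_index]
        return generate_reads(
            pool,
            campaign.reads_per_round,
            campaign.per_base_error_rate,
            barcode,
            rng if rng is not None else np.random.default_rng(0),
        )

    if campaign.reads_per_round > 0:
        rna_reads[0] = _reads(rna_pool, campaign.rna_barcodes, 0)
        protein_reads[0] = _reads(phage_pool, campaign.protein_barcodes, 0)

    current_rna, current_phage = rna_pool, phage_pool
    for r, cfg in enumerate(campaign.rounds, start=1):
        result = simulate_round(current_rna, current_phage, landscape, cfg, mode, rng)
        if result.crashed:
            raise SelectionCrash(r, result.crashed_pool or "rna")
        next_cfg = campaign.rounds[r] if r < len(campaign.rounds) else cfg
        current_rna = amplify(
            result.captured_rna, next_cfg.rna_input, amplification_noise_sd, rng, mode
        )
        current_phage = amplify(
            result.captured_phage, next_cfg.phage_input, amplification_noise_sd, rng, mode
        )
        rna_pools.append(current_rna)
        phage_pools.append(current_phage)
        logs.append(result.log)
        if campaign.reads_per_round > 0:
            rna_reads[r] = _reads(current_rna, campaign.rna_barcodes, r)
            protein_reads[r] = _reads(current_phage, campaign.protein_barcodes, r)

    return CampaignResult(
        rna_pools, phage_pools, logs, rna_reads, protein_reads, landscape,
        truth or {},
    )


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

_DNA = np.array(list("ACGT"))
_DNA_INDEX = {b: i for i, b in enumerate("ACGT")}


def _mutate_batch(template: str, k: int, error_rate: float, rng) -> list[str]:
    """k copies of template with independent per-base substitutions."""
    length = len(template)
    idx = np.array([_DNA_INDEX.get(b, 0) for b in template], dtype=np.int8)
    mat = np.tile(idx, (k, 1))
    if error_rate > 0:
        mask = rng.random((k, length)) < error_rate
        n_err = int(mask.sum())
        if n_err:
            # shift by 1-3 mod 4 => always a different base
            mat[mask] = (mat[mask] + rng.integers(1, 4, size=n_err)) % 4
    chars = _DNA[mat]
    return ["".join(row) for row in chars]


def generate_reads(
    pool: Pool,
    n_reads: int,
    per_base_error_rate: float,
    barcode: str,
    rng: np.random.Generator,
) -> list:
    """Sample FASTQ records from a pool.

    Templates are drawn multinomially by abundance; substitution errors are
    independent per base (no indels — the variable regions are short and
    flank-anchored); the barcode is prepended before error injection and the
    quality string is constant.
    """
    from .io import FastqRecord

    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0:
        return []
    if pool.templates is None:
        raise ValueError("pool has no read templates")
    counts = rng.multinomial(n_reads, pool.abundances)
    records: list[FastqRecord] = []
    read_no = 0
    bc = barcode.upper().replace("U", "T")
    for i, k in enumerate(counts):
        if k == 0:
            continue
        template = bc + pool.templates[i]
        for seq in _mutate_batch(template, int(k), per_base_error_rate, rng):
            records.append(
                FastqRecord(f"read_{read_no}", seq, "I" * len(seq))
            )
            read_no += 1
    return records


# ---------------------------------------------------------------------------
# study builders (the synthetic-data presets)
# ---------------------------------------------------------------------------


def default_campaign_schedule(n_rounds: int = 6) -> list[RoundConfig]:
    """Six-round stringency schedule: negative selection in rounds 1-2,
    urea in the last two rounds, inputs decreasing and washes increasing
    monotonically.  The per-round laboratory parameters are not public, so
    these values are placeholders encoding only the stated structure; every
    field is overridable.
    """
    rounds = []
    for r in range(n_rounds):
        rounds.append(
            RoundConfig(
                rna_input=1e7 / (2**r),
                phage_input=1e7 / (2**r),
                binding_time=1800.0 / (1 + r),
                n_washes=3 + r,
                urea=r >= n_rounds - 2,
                negative_selection=r < 2,
                effective_protein_conc=1e-9 / (2**r),
            )
        )
    return rounds


def _random_rna(rng, length: int = 20) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])


def _random_protein(rng, length: int = 8) -> str:
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(aas[rng.integers(0, 20, size=length)])


def _rna_template(design: RnaLibraryDesign, variable: str) -> str:
    rna = design.fixed_5p + variable + design.fixed_3p
    return rna.replace("U", "T")


def mock_mixture_study(
    binder_fraction: float = 0.01,
    cognate_kd: float = 2.13e-11,
    total_rna: float = 1e6,
    total_phage: float = 1e6,
):
    """The mixture experiment: a cognate RNA/protein pair spiked at 1:99
    into defective non-binding counterparts on both sides.

    Returns ``(rna_pool, phage_pool, landscape, round_config)``.  The
    cognate pair's kinetics follow the model pair (k_off 2.77e-4 1/s with
    k_on chosen to give the requested K_D); the defective variants do not
    bind anything.
    """
    f = binder_fraction
    rna_pool = Pool(
        kind="rna",
        ids=["Kt", "dKt"],
        sequences=["GAUGAUC", "GAUGAUCAAUCG"],
        counts=np.array([f, 1 - f]) * total_rna,
    )
    phage_pool = Pool(
        kind="protein",
        ids=["L7Ae", "dL7Ae"],
        sequences=["EKERIEVP", "KEGGGGGS"],
        counts=np.array([f, 1 - f]) * total_phage,
    )
    k_off = 2.77e-4
    landscape = KdLandscape()
    landscape.add("Kt", "L7Ae", k_off / cognate_kd, k_off)
    cfg = RoundConfig(
        rna_input=total_rna,
        phage_input=total_phage,
        n_washes=3,
        effective_protein_conc=1e-9,
        capture_eff_step1=0.5,
        capture_eff_step2=0.5,
        background_step1=1e-3,
        background_step2=1e-3,
        rnaseh_specificity=0.1,
    )
    return rna_pool, phage_pool, landscape, cfg


def planted_pair_study(
    rng: np.random.Generator,
    rna_design: RnaLibraryDesign,
    protein_design: ProteinLibraryDesign,
    n_rna: int = 10_000,
    n_protein: int = 100,
    n_siblings: int = 40,
    planted_kd: float = 1e-11,
    sibling_kd: float = 1e-8,
    off_target_kd: float = 1e-6,
    n_rounds: int = 3,
    reads_per_round: int = 100_000,
    motif: str = "UUGUGASGC",
    rna_barcodes: list[str] | None = None,
    protein_barcodes: list[str] | None = None,
):
    """Campaign with one planted cognate RNA-protein pair.

    The planted RNA carries a consensus motif and binds the planted protein
    at ``planted_kd`` (10 pM by default); a family of motif-carrying sibling
    RNAs binds it three orders of magnitude more weakly, mirroring the
    consensus-family structure of real selections; every other RNA-protein
    combination shares a uniform weak ``off_target_kd`` (1 uM).  Rounds are
    run at decreasing effective concentration with bottlenecks, and reads
    are emitted for all sequenced pools.

    Returns ``(CampaignConfig, rna_pool, phage_pool, landscape, truth)``.
    """
    motif_pat = MotifPattern(motif)
    bases = np.array(list("ACGU"))

    def _embed(m: str) -> str:
        pad = rna_design.variable_length - len(m)
        start = int(rng.integers(0, pad + 1))
        left = "".join(bases[rng.integers(0, 4, size=start)])
        right = "".join(bases[rng.integers(0, 4, size=pad - start)])
        return left + m + right

    planted_rna_seq = _embed(motif_pat.pattern.replace("S", "C"))
    rna_seqs = {planted_rna_seq}
    sibling_seqs = []
    while len(sibling_seqs) < n_siblings:
        s_char = "C" if rng.random() < 0.5 else "G"
        seq = _embed(motif_pat.pattern.replace("S", s_char))
        if seq not in rna_seqs:
            rna_seqs.add(seq)
            sibling_seqs.append(seq)
    while len(rna_seqs) < n_rna:
        rna_seqs.add(_random_rna(rng, rna_design.variable_length))
    others = sorted(rna_seqs - {planted_rna_seq} - set(sibling_seqs))
    all_rna = [planted_rna_seq] + sibling_seqs + others

    prot_seqs: set[str] = set()
    while len(prot_seqs) < n_protein:
        prot_seqs.add(_random_protein(rng))
    all_prot = sorted(prot_seqs)
    planted_prot_seq = all_prot[int(rng.integers(len(all_prot)))]

    rna_ids = [f"R{i:05d}" for i in range(len(all_rna))]
    prot_ids = [f"P{j:03d}" for j in range(len(all_prot))]
    planted_rna_id = rna_ids[0]
    planted_prot_id = prot_ids[all_prot.index(planted_prot_seq)]

    rna_pool = Pool(
        kind="rna",
        ids=rna_ids,
        sequences=all_rna,
        counts=np.full(len(all_rna), 100.0),
        templates=[_rna_template(rna_design, s) for s in all_rna],
    )
    phage_pool = Pool(
        kind="protein",
        ids=prot_ids,
        sequences=all_prot,
        counts=np.full(len(all_prot), 10_000.0),
        templates=[encode_variable_region(s, protein_design, rng) for s in all_prot],
    )

    landscape = KdLandscape(default_kd=off_target_kd)
    k_off = 1e-4
    landscape.add(planted_rna_id, planted_prot_id, k_off / planted_kd, k_off)
    for rid in rna_ids[1 : 1 + n_siblings]:
        landscape.add(rid, planted_prot_id, k_off / sibling_kd, k_off)

    rounds = [
        RoundConfig(
            rna_input=rna_pool.total,
            phage_input=phage_pool.total,
            n_washes=3 + r,
            effective_protein_conc=1e-10,
            effective_rna_conc=1e-8,
            avidity_copies=10,
            background_step1=1e-4,
            background_step2=1e-4,
            bottleneck_rna=200_000,
            bottleneck_phage=200_000,
        )
        for r in range(n_rounds)
    ]
    campaign = CampaignConfig(
        rounds=rounds,
        rna_design=rna_design,
        protein_design=protein_design,
        reads_per_round=reads_per_round,
        per_base_error_rate=0.001,
        rna_barcodes=rna_barcodes,
        protein_barcodes=protein_barcodes,
    )
    truth = {
        "planted_rna_id": planted_rna_id,
        "planted_rna_sequence": planted_rna_seq,
        "planted_protein_id": planted_prot_id,
        "planted_protein_sequence": planted_prot_seq,
        "sibling_rna_ids": rna_ids[1 : 1 + n_siblings],
        "motif": motif_pat.pattern,
    }
    return campaign, rna_pool, phage_pool, landscape, truth
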