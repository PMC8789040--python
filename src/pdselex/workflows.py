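"""End-to-end study workflows tying the modules together.

These functions define the package's reference studies: a planted-pair
selection campaign followed by the full NGS analysis and deconvolution, the
mixture (mock-selection) enrichment check, and Langmuir simulate-then-fit
recovery studies.  They are what the command-line entry points, the test
suite and the reproduction script all run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import deconvolution as dc
from . import enrichment as en
from . import kinetics as kin
from . import simulate as sim
from .io import stage_rng
from .library import MotifPattern, load_preset, motif_match

__all__ = [
    "DEFAULT_BARCODES",
    "langmuir_noise_study",
    "langmuir_noiseless_grid",
    "mock_mixture_expectation",
    "run_planted_pair_study",
]

#: 8-nt round barcodes, pairwise Hamming distance >= 4
DEFAULT_BARCODES = (
    "AACCGGTT", "CCAATTGG", "GGTTAACC", "TTGGCCAA",
    "ACGTACGT", "CAGTCAGT", "GTACGTAC", "TCATGCAG",
)


# ---------------------------------------------------------------------------
# planted-pair campaign + analysis + deconvolution
# ---------------------------------------------------------------------------


def run_planted_pair_study(
    seed: int,
    n_rna: int = 10_000,
    n_protein: int = 100,
    n_rounds: int = 3,
    reads_per_round: int = 100_000,
    focused_library_size: int = 1991,
    n_controls: int = 9,
    top_n_proteins: int = 20,
) -> dict:
    """Simulate a library-vs-library campaign with one planted cognate pair
    and analyse it end to end.

    Pipeline: simulate the campaign with barcoded reads -> demultiplex reads
    by round -> extract RNA variable regions / translate protein variable
    residues -> count tables -> motif fractions, monotonic-EF filter and
    top-N ranking -> focused-library re-selection against the top proteins
    -> motif-subset box statistics and cognate/depleted calls.

    The focused library mirrors the re-selection design: the most abundant
    post-selection RNAs plus spiked control RNAs that bind every
    scaffold-derived protein weakly (K_D tens of nM) — the property that
    makes non-cognate arms deplete rather than merely not enrich the motif
    subset.

    Returns a dictionary of analysis results plus the ground truth.
    """
    rna_design, protein_design = load_preset()
    rng = stage_rng(seed, "campaign")
    barcodes = list(DEFAULT_BARCODES[: n_rounds + 1])
    campaign, rna_pool, phage_pool, landscape, truth = sim.planted_pair_study(
        rng,
        rna_design,
        protein_design,
        n_rna=n_rna,
        n_protein=n_protein,
        n_rounds=n_rounds,
        reads_per_round=reads_per_round,
        rna_barcodes=barcodes,
        protein_barcodes=barcodes,
    )
    result = sim.simulate_campaign(
        campaign, rna_pool, phage_pool, landscape, mode="stochastic", rng=rng
    )

    # --- read-level analysis: demultiplex by round barcode, then count ----
    barcode_map = {str(r): barcodes[r] for r in range(n_rounds + 1)}
    all_rna_reads = [rec for recs in result.rna_reads.values() for rec in recs]
    all_prot_reads = [rec for recs in result.protein_reads.values() for rec in recs]
    rna_bins = en.demultiplex(all_rna_reads, barcode_map, max_mismatch=1)
    prot_bins = en.demultiplex(all_prot_reads, barcode_map, max_mismatch=1)

    bclen = len(barcodes[0])
    table = en.CountTable()
    for r in range(n_rounds + 1):
        seqs, _ = en.count_rna_reads(rna_bins[str(r)], rna_design, barcode_len=bclen)
        table.add("rna", r, seqs)
        aas, _ = en.count_protein_reads(
            prot_bins[str(r)], protein_design, barcode_len=bclen
        )
        table.add("protein", r, aas)

    # --- pool-level summaries ---------------------------------------------
    motif = MotifPattern(truth["motif"], name="consensus1")
    motif_fractions = [
        en.motif_fraction(table, "rna", r, motif) for r in range(n_rounds + 1)
    ]
    top_rna = en.top_n(table, "rna", n_rounds, n=1)
    survivors = en.filter_monotonic_enrichment(
        table, "protein", (n_rounds - 2, n_rounds - 1, n_rounds), threshold=1.0
    )
    top_proteins = en.top_n(table, "protein", n_rounds, n=top_n_proteins)
    ranked_protein_counts = table.counts("protein", n_rounds)

    # --- deconvolution by re-selection ------------------------------------
    seq_to_prot_id = dict(zip(phage_pool.sequences, phage_pool.ids))
    seq_to_rna_id = dict(zip(rna_pool.sequences, rna_pool.ids))
    rna_id_to_seq = dict(zip(rna_pool.ids, rna_pool.sequences))

    # the focused library is synthesized at a fixed size: the most abundant
    # post-selection species, padded with pre-selection species when the
    # selected pool has collapsed below that size
    focused = [
        s for s in table.counts("rna", n_rounds).index if s in seq_to_rna_id
    ][:focused_library_size]
    if len(focused) < focused_library_size:
        seen = set(focused)
        for s in table.counts("rna", 0).index:
            if s in seq_to_rna_id and s not in seen:
                focused.append(s)
                seen.add(s)
                if len(focused) >= focused_library_size:
                    break
    rng_dc = stage_rng(seed, "deconvolution")
    controls = []
    while len(controls) < n_controls:
        seq = "".join(np.array(list("ACGU"))[rng_dc.integers(0, 4, size=20)])
        if seq not in focused and not motif_match(seq, motif):
            controls.append(seq)
    library = focused + controls
    pre_counts = pd.Series(1_000, index=library)

    arms: dict[str, dict[str, float]] = {}
    for prot_seq in top_proteins:
        pid = seq_to_prot_id.get(prot_seq)
        kd_map: dict[str, float] = {}
        if pid is not None:
            for (rid, p), (k_on, k_off) in landscape.items():
                if p == pid and rid in rna_id_to_seq:
                    kd_map[rna_id_to_seq[rid]] = k_off / k_on
        # control RNAs bind every scaffold-derived arm weakly (5-20 nM)
        for c in controls:
            kd_map[c] = 10.0 ** rng_dc.uniform(-8.3, -7.7)
        arms[prot_seq] = kd_map

    experiment = dc.simulate_reselection(
        pre_counts,
        arms,
        effective_conc=3e-9,
        read_depth=100_000,
        rng=rng_dc,
        control_ids=controls,
        default_kd=landscape.default_kd,
    )
    subset = dc.motif_subset(library, motif, exclude=controls)
    stats = []
    for prot_seq in arms:
        efs = dc.reselection_ef(experiment, prot_seq)
        stats.append(
            dc.subset_box_stats(efs, subset, protein_id=prot_seq,
                                subset_label="consensus1")
        )
    calls = dc.call_pairs(stats)

    planted_rna_seq = truth["planted_rna_sequence"]
    planted_prot_seq = truth["planted_protein_sequence"]
    cognate_arms = [p for (p, s), v in calls.calls.items() if v == "cognate"]
    try:
        planted_rank = list(ranked_protein_counts.index).index(planted_prot_seq) + 1
    except ValueError:
        planted_rank = None

    return {
        "truth": truth,
        "table": table,
        "motif_fractions": motif_fractions,
        "top_rna_sequence": top_rna[0],
        "top_rna_is_planted": top_rna[0] == planted_rna_seq,
        "protein_filter_survivors": survivors,
        "planted_protein_survives_filter": planted_prot_seq in survivors,
        "top_proteins": top_proteins,
        "planted_protein_rank": planted_rank,
        "planted_protein_in_top": planted_prot_seq in top_proteins,
        "calls": calls,
        "cognate_arms": cognate_arms,
        "planted_arm_cognate": planted_prot_seq in cognate_arms,
        "n_false_cognate_arms": len([a for a in cognate_arms
                                     if a != planted_prot_seq]),
        "experiment": experiment,
        "box_stats": stats,
    }


# ---------------------------------------------------------------------------
# mixture (mock-selection) expectation check
# ---------------------------------------------------------------------------


def mock_mixture_expectation(binder_fraction: float = 0.01) -> dict:
    """Expectation-mode single round of the 1:99 mixture experiment.

    Returns the simulated post-round binder fractions and enrichment
    factors for both pools together with the per-molecule retention
    probabilities, so callers can verify the closed-form mixture identity
    f' = f p_b / (f p_b + (1-f) p_nb) independently.
    """
    rna_pool, phage_pool, landscape, cfg = sim.mock_mixture_study(binder_fraction)
    p_binder = sim.capture_probability("Kt", phage_pool, landscape, cfg)
    p_nonbinder = sim.capture_probability("dKt", phage_pool, landscape, cfg)
    result = sim.simulate_round(rna_pool, phage_pool, landscape, cfg,
                                mode="expectation")
    rna_ab = result.captured_rna.abundances
    phage_ab = result.captured_phage.abundances
    f = binder_fraction
    return {
        "p_binder": p_binder,
        "p_nonbinder": p_nonbinder,
        "rna_binder_fraction_post": float(rna_ab[0]),
        "rna_enrichment": float(rna_ab[0]) / f,
        "phage_binder_fraction_post": float(phage_ab[0]),
        "phage_enrichment": float(phage_ab[0]) / f,
    }


# ---------------------------------------------------------------------------
# Langmuir recovery studies
# ---------------------------------------------------------------------------


def _conc_series(k_d: float, n: int = 5, lo: float = 0.3, hi: float = 30.0):
    return np.geomspace(lo * k_d, hi * k_d, n)


def _phase_plan(k_on: float, k_off: float, conc_max: float):
    """Phase durations resolving both phases, with a bounded point count."""
    k_obs = conc_max * k_on + k_off
    t_assoc = float(np.clip(3.0 / k_obs, 100.0, 2000.0))
    t_diss = float(np.clip(2.0 / k_off, 420.0, 50_000.0))
    dt_a = max(t_assoc / 400.0, 0.25)
    dt = max(t_diss / 400.0, dt_a)
    return t_assoc, t_diss, dt


def _recovery_error(true_params: kin.LangmuirParams,
                    fit: kin.KineticFitResults) -> float:
    return max(
        abs(fit.k_on - true_params.k_on) / true_params.k_on,
        abs(fit.k_off - true_params.k_off) / true_params.k_off,
    )


def langmuir_noiseless_grid(
    kon_grid=(1e5, 1e6, 1.41e7, 2.00e7),
    koff_grid=(1e-5, 1.36e-4, 2.77e-4, 1e-2),
    r_max: float = 100.0,
) -> pd.DataFrame:
    """Simulate-then-fit over a rate grid with noiseless curves.

    Returns a frame of relative recovery errors (max over k_on and k_off)
    per grid point.  The grid includes the measured rate constants of the
    model pair and the two selected pairs.
    """
    rows = []
    for k_on in kon_grid:
        for k_off in koff_grid:
            true = kin.LangmuirParams(k_on, k_off, r_max)
            t_assoc, t_diss, dt = _phase_plan(k_on, k_off, 30.0 * true.k_d)
            sgs = kin.simulate_sensorgrams(
                true, _conc_series(true.k_d), t_assoc=t_assoc, t_diss=t_diss,
                dt=dt,
            )
            fit = kin.LangmuirModel(sgs).fit()
            rows.append(
                {
                    "k_on": k_on,
                    "k_off": k_off,
                    "rel_error": _recovery_error(true, fit),
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def langmuir_noise_study(
    seed: int,
    n_seeds: int = 50,
    k_on: float = 2.00e7,
    k_off: float = 1.36e-4,
    r_max: float = 100.0,
    noise_fraction: float = 0.01,
) -> pd.DataFrame:
    """Monte-Carlo recovery with Gaussian noise at a fraction of R_max,
    5 concentrations spanning 0.1-10 x K_D.  Returns per-seed errors."""
    true = kin.LangmuirParams(k_on, k_off, r_max)
    concs = np.geomspace(0.1 * true.k_d, 10.0 * true.k_d, 5)
    t_assoc, t_diss, dt = _phase_plan(k_on, k_off, concs[-1])
    rows = []
    for i in range(n_seeds):
        rng = stage_rng(seed, f"langmuir_noise_{i}")
        sgs = kin.simulate_sensorgrams(
            true, concs, t_assoc=t_assoc, t_diss=t_diss, dt=dt,
            noise_sd=noise_fraction * r_max, rng=rng,
        )
        fit = kin.LangmuirModel(sgs).fit()
        rows.append({"seed_index": i, "rel_error": _recovery_error(true, fit)})
    return pd.DataFrame(rows)
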