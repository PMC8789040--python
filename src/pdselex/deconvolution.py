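"""Re-selection deconvolution: assigning RNA motifs to cognate proteins.

A focused RNA library (the most abundant post-selection species plus
labelled control RNAs) is selected against each candidate protein
individually.  Per-RNA enrichment factors (abundance after / before) are
summarized for motif-defined subsets by box statistics, and each
(protein, subset) is called cognate (median >= 1.0), depleted
(median < 0.5) or neutral; mutually orthogonal pairs are proposed when two
proteins are cognate for different subsets and depleted for each other's.

The thresholds mirror how enrichment and depletion are read off re-selection
box plots; because "significant" enrichment has no named test here, medians
are accompanied by a seeded bootstrap interval rather than a p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import MotifPattern, motif_match

__all__ = [
    "EfBoxStats",
    "PairCall",
    "ReselectionExperiment",
    "bootstrap_median_interval",
    "call_pairs",
    "reselection_ef",
    "simulate_reselection",
    "subset_box_stats",
]


@dataclass
class ReselectionExperiment:
    """Pre-selection pool counts and one post-selection table per protein.

    ``pre_counts``/``post_counts`` are sequence -> count series; every post
    species should be a subset of the pre species after extraction.
    ``control_ids`` labels spiked-in control RNAs.
    """

    pre_counts: pd.Series
    post_counts: dict[str, pd.Series]
    control_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.pre_counts <= 0).all():
            raise ValueError("pre-selection pool is empty")
        self.control_ids = frozenset(self.control_ids)

    def proteins(self) -> list[str]:
        return sorted(self.post_counts)


def reselection_ef(
    experiment: ReselectionExperiment, protein_id: str
) -> pd.Series:
    """Per-RNA EF against one protein arm: abundance_post / abundance_pre.

    Species absent after selection get EF 0.  Species observed post but
    absent from the pre table are undefined and excluded with a warning.
    """
    post = experiment.post_counts[protein_id]
    pre = experiment.pre_counts[experiment.pre_counts > 0]
    novel = post.index.difference(pre.index)
    if len(novel) > 0:
        warnings.warn(
            f"{len(novel)} species in the {protein_id} post table are absent "
            "from the pre table; their EF is undefined and they are excluded",
            stacklevel=2,
        )
        post = post.drop(novel)
    pre_ab = pre / pre.sum()
    post_ab = post / post.sum() if post.sum() > 0 else post.astype(float)
    return post_ab.reindex(pre_ab.index, fill_value=0.0) / pre_ab


@dataclass(frozen=True)
class EfBoxStats:
    """Box-plot statistics of a subset's EFs (quartiles by linear
    interpolation; whiskers at 1.5 x IQR clamped to the data range)."""

    protein_id: str
    subset: str
    n: int
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    whisker_low: float | None = None
    whisker_high: float | None = None

    @property
    def empty(self) -> bool:
        return self.n == 0


def subset_box_stats(
    efs: pd.Series,
    subset_ids,
    protein_id: str = "",
    subset_label: str = "",
) -> EfBoxStats:
    """Box statistics over ``efs`` restricted to ``subset_ids``."""
    values = efs.reindex([i for i in subset_ids if i in efs.index]).dropna()
    values = values.to_numpy(dtype=float)
    if values.size == 0:
        return EfBoxStats(protein_id, subset_label, 0)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = max(values.min(), q1 - 1.5 * iqr)
    hi = min(values.max(), q3 + 1.5 * iqr)
    return EfBoxStats(
        protein_id, subset_label, int(values.size),
        float(med), float(q1), float(q3), float(lo), float(hi),
    )


def bootstrap_median_interval(
    values, n_resamples: int = 10_000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for the median."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class PairCall:
    """Calls per (protein, subset) plus proposed orthogonal pairs."""

    calls: dict[tuple[str, str], str]
    orthogonal_pairs: list[tuple[tuple[str, str], tuple[str, str]]]
    enriched_median_min: float
    depleted_ef_max: float

    def cognate_pairs(self) -> list[tuple[str, str]]:
        return sorted(k for k, v in self.calls.items() if v == "cognate")


def call_pairs(
    box_stats: list[EfBoxStats],
    enriched_median_min: float = 1.0,
    depleted_ef_max: float = 0.5,
) -> PairCall:
    """Call each (protein, subset) cognate / depleted / neutral by the
    subset's median EF (cognate at median >= ``enriched_median_min``,
    boundary inclusive; depleted below ``depleted_ef_max``).

    Orthogonal pairs: (A, s1) and (B, s2) are proposed when A is cognate
    for s1 and depleted for s2 while B is cognate for s2 and depleted
    for s1.
    """
    calls: dict[tuple[str, str], str] = {}
    for st in box_stats:
        if st.empty:
            raise ValueError(
                f"empty subset {st.subset!r} for protein {st.protein_id!r}"
            )
        if st.median >= enriched_median_min:
            call = "cognate"
        elif st.median < depleted_ef_max:
            call = "depleted"
        else:
            call = "neutral"
        calls[(st.protein_id, st.subset)] = call

    proteins = sorted({p for p, _ in calls})
    subsets = sorted({s for _, s in calls})
    orthogonal = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            for j, s1 in enumerate(subsets):
                for s2 in subsets[j + 1 :]:
                    fwd = (
                        calls.get((a, s1)) == "cognate"
                        and calls.get((a, s2)) == "depleted"
                        and calls.get((b, s2)) == "cognate"
                        and calls.get((b, s1)) == "depleted"
                    )
                    rev = (
                        calls.get((a, s2)) == "cognate"
                        and calls.get((a, s1)) == "depleted"
                        and calls.get((b, s1)) == "cognate"
                        and calls.get((b, s2)) == "depleted"
                    )
                    if fwd:
                        orthogonal.append(((a, s1), (b, s2)))
                    elif rev:
                        orthogonal.append(((a, s2), (b, s1)))
    return PairCall(calls, orthogonal, enriched_median_min, depleted_ef_max)


def motif_subset(sequences, pattern: MotifPattern | str, exclude=()) -> list:
    """IDs/sequences containing the motif, minus explicit exclusions."""
    if not isinstance(pattern, MotifPattern):
        pattern = MotifPattern(pattern)
    excluded = set(exclude)
    return [s for s in sequences if s not in excluded and motif_match(s, pattern)]


# ---------------------------------------------------------------------------
# re-selection simulation (single-protein arms)
# ---------------------------------------------------------------------------


def simulate_reselection(
    pre_counts: pd.Series,
    arms: dict[str, dict[str, float]],
    effective_conc: float = 1e-8,
    capture_eff: float = 0.5,
    background: float = 1e-4,
    n_washes: int = 8,
    wash_loss: float = 0.5,
    read_depth: int | None = 100_000,
    rng: np.random.Generator | None = None,
    control_ids=(),
    default_kd: float | None = None,
) -> ReselectionExperiment:
    """Single-protein selection of a focused library against each arm.

    ``arms`` maps protein_id -> {rna_id: K_D}; RNAs absent from an arm's
    map bind it at ``default_kd`` (None = no specific binding).  Recombinant
    protein on beads is monovalent, so no avidity correction applies.
    Retention per RNA is
    ``capture_eff * C/(C+K_D) + background * (1-wash_loss)**n_washes``;
    with ``read_depth`` set, post pools are multinomially sampled to that
    depth (expectation counts otherwise).
    """
    pre = pre_counts[pre_counts > 0].astype(float)
    bg = background * (1.0 - wash_loss) ** n_washes
    post: dict[str, pd.Series] = {}
    for protein_id, kd_map in arms.items():
        kd = pre.index.map(lambda r: kd_map.get(r, default_kd))
        theta = np.array(
            [0.0 if k is None else effective_conc / (effective_conc + k) for k in kd]
        )
        p = np.minimum(1.0, capture_eff * theta + bg)
        retained = pre.to_numpy() * p
        if read_depth is not None:
            if rng is None:
                raise ValueError("read_depth sampling requires an rng")
            probs = retained / retained.sum()
            sampled = rng.multinomial(int(read_depth), probs)
            post[protein_id] = pd.Series(sampled, index=pre.index)
        else:
            post[protein_id] = pd.Series(retained, index=pre.index)
    return ReselectionExperiment(pre, post, frozenset(control_ids))
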