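"""Posterior change classification between pairs of time bins.

For each grid cell, taxon and pair of times, differences in proportional
abundance are computed within each posterior draw.  A change is
*statistically significant* when its directional posterior probability
reaches 0.85, and *ecologically significant* only if the taxon's
posterior-mean abundance exceeds 3% at one of the two times.  Beyond
direction, each taxon is tested for statistically significant *large
change* (|difference| above the 5% threshold with probability >= 0.85) and
significant *stability* (|difference| below the 3% threshold with
probability >= 0.85).  At the community level a cell is a large-change cell
if any taxon shows large change (the dominant taxon being the large-changer
with the greatest posterior-mean |difference|), a stable cell if every
taxon is significantly stable, and otherwise neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .prediction import PosteriorEnsemble

__all__ = [
    "ChangeThresholds",
    "TaxonChangeFlags",
    "ChangeClassification",
    "pairwise_diff",
    "directional_probability",
    "classify_taxon",
    "classify_community",
    "summarize_domain",
    "classify_pair",
]

COMMUNITY_LABELS = ("neither", "large_change", "stable_all")


@dataclass(frozen=True)
class ChangeThresholds:
    """Classification thresholds (posterior probability and abundance cuts)."""

    prob_cut: float = 0.85
    eco_cut: float = 0.03
    large_cut: float = 0.05
    stability_cut: float = 0.03

    def __post_init__(self) -> None:
        for name in ("prob_cut", "eco_cut", "large_cut", "stability_cut"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def pairwise_diff(ensemble: PosteriorEnsemble, t1: int, t2: int,
                  source: str = "process_mean") -> np.ndarray:
    """Per-draw differences r[., t2, .] - r[., t1, .], shape (D, N, K).

    Computed within each posterior draw so that the full joint uncertainty
    propagates into every derived probability.
    """
    draws = ensemble.composition_draws(source)
    T = draws.shape[2]
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    for t in (t1, t2):
        if not 0 <= t < T:
            raise ValueError(f"time bin {t} outside ensemble range 0..{T - 1}")
    return draws[:, :, t2, :] - draws[:, :, t1, :]


def directional_probability(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical P(diff > 0) and P(diff < 0) over the draw axis (axis 0).

    Exact zeros count toward neither direction.
    """
    diffs = np.asarray(diffs)
    if diffs.shape[0] < 2:
        raise ValueError("need at least two draws")
    p_up = np.mean(diffs > 0, axis=0)
    p_down = np.mean(diffs < 0, axis=0)
    return p_up, p_down


@dataclass
class TaxonChangeFlags:
    """Per-(cell, taxon) outcomes for one time pair."""

    p_change: np.ndarray       # (N, K) max directional probability
    direction: np.ndarray      # (N, K) sign of the more probable direction
    significant: np.ndarray    # (N, K) bool, directional + ecological filter
    large_change: np.ndarray   # (N, K) bool
    stable: np.ndarray         # (N, K) bool
    mean_diff: np.ndarray      # (N, K) posterior-mean difference


def classify_taxon(
    diffs: np.ndarray,
    abund_t1: np.ndarray,
    abund_t2: np.ndarray,
    thresholds: ChangeThresholds = ChangeThresholds(),
) -> TaxonChangeFlags:
    """Classify each (cell, taxon) from per-draw differences.

    ``abund_t1``/``abund_t2`` are posterior-mean abundances (N, K) at the
    two times, used for the 3% ecological filter.
    """
    th = thresholds
    p_up, p_down = directional_probability(diffs)
    p_change = np.maximum(p_up, p_down)
    direction = np.where(p_up >= p_down, 1, -1)
    eco = (abund_t1 > th.eco_cut) | (abund_t2 > th.eco_cut)
    significant = (p_change >= th.prob_cut) & eco
    large = np.mean(np.abs(diffs) > th.large_cut, axis=0) >= th.prob_cut
    stable = np.mean(np.abs(diffs) < th.stability_cut, axis=0) >= th.prob_cut
    return TaxonChangeFlags(
        p_change=p_change, direction=direction, significant=significant,
        large_change=large & eco, stable=stable, mean_diff=diffs.mean(axis=0),
    )


def classify_community(flags: TaxonChangeFlags) -> tuple[np.ndarray, np.ndarray]:
    """Community label per cell and the dominant taxon index.

    Returns (labels, dominant): labels in {'large_change', 'stable_all',
    'neither'}; dominant is the large-change taxon with greatest
    posterior-mean |difference| (-1 where no taxon shows large change).
    """
    any_large = flags.large_change.any(axis=1)
    all_stable = flags.stable.all(axis=1)
    labels = np.where(any_large, "large_change",
                      np.where(all_stable, "stable_all", "neither"))
    masked = np.where(flags.large_change, np.abs(flags.mean_diff), -np.inf)
    dominant = np.where(any_large, np.argmax(masked, axis=1), -1)
    return labels, dominant


def summarize_domain(labels: np.ndarray) -> dict[str, float]:
    """Percent of grid cells unstable (US, large change) and stable (S)."""
    n = len(labels)
    return {
        "percent_unstable": 100.0 * np.count_nonzero(labels == "large_change") / n,
        "percent_stable": 100.0 * np.count_nonzero(labels == "stable_all") / n,
    }


@dataclass
class ChangeClassification:
    """Full classification for a set of time pairs."""

    pairs: list
    flags: dict = field(default_factory=dict)          # (t1, t2) -> TaxonChangeFlags
    labels: dict = field(default_factory=dict)         # (t1, t2) -> (N,) labels
    dominant: dict = field(default_factory=dict)       # (t1, t2) -> (N,) int
    taxa: tuple[str, ...] = ()
    bin_mid: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> pd.DataFrame:
        rows = []
        for (t1, t2) in self.pairs:
            s = summarize_domain(self.labels[(t1, t2)])
            rows.append({
                "t1_yb1950": self.bin_mid[t1], "t2_yb1950": self.bin_mid[t2],
                **s,
            })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long per-(pair, cell, taxon) table of flags."""
        rows = []
        for (t1, t2), fl in self.flags.items():
            N, K = fl.p_change.shape
            for k, tx in enumerate(self.taxa):
                rows.append(pd.DataFrame({
                    "t1_yb1950": self.bin_mid[t1], "t2_yb1950": self.bin_mid[t2],
                    "cell": np.arange(N), "taxon": tx,
                    "p_change": fl.p_change[:, k],
                    "mean_diff": fl.mean_diff[:, k],
                    "significant": fl.significant[:, k],
                    "large_change": fl.large_change[:, k],
                    "stable": fl.stable[:, k],
                }))
        return pd.concat(rows, ignore_index=True)


def classify_pair(
    ensemble: PosteriorEnsemble,
    t1: int,
    t2: int,
    thresholds: ChangeThresholds = ChangeThresholds(),
    source: str = "process_mean",
) -> tuple[TaxonChangeFlags, np.ndarray, np.ndarray]:
    """Classify one pair of time bins from an ensemble."""
    diffs = pairwise_diff(ensemble, t1, t2, source=source)
    draws = ensemble.composition_draws(source)
    flags = classify_taxon(diffs, draws[:, :, t1, :].mean(axis=0),
                           draws[:, :, t2, :].mean(axis=0), thresholds)
    labels, dominant = classify_community(flags)
    return flags, labels, dominant


def classify_all_pairs(
    ensemble: PosteriorEnsemble,
    thresholds: ChangeThresholds = ChangeThresholds(),
    pairs: Iterable[tuple[int, int]] | None = None,
    source: str = "process_mean",
) -> ChangeClassification:
    """Classification over all pairwise combinations of time bins (or a
    provided subset)."""
    T = ensemble.r.shape[2]
    pairs = list(pairs) if pairs is not None else [
        (t1, t2) for t1 in range(T) for t2 in range(t1 + 1, T)
    ]
    out = ChangeClassification(pairs=pairs, taxa=ensemble.taxa, bin_mid=ensemble.bin_mid)
    for (t1, t2) in pairs:
        flags, labels, dominant = classify_pair(ensemble, t1, t2, thresholds, source)
        out.flags[(t1, t2)] = flags
        out.labels[(t1, t2)] = labels
        out.dominant[(t1, t2)] = dominant
    return out
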